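import numpy as np
import pytest

from immunoqsp.model_config import (
    default_model,
    default_scenario,
)
from immunoqsp.binding import build_checkpoint_binding, surface_concentration


@pytest.fixture(scope="session")
def model():
    """Shipped default parameterization (registry, profiles)."""
    return default_model()


@pytest.fixture(scope="session")
def registry(model):
    return model[0]


@pytest.fixture(scope="session")
def profiles(model):
    return model[1]


@pytest.fixture(scope="session")
def checkpoint_network(registry, profiles):
    return build_checkpoint_binding(profiles, registry)


@pytest.fixture(scope="session")
def invivo_totals(registry, profiles):
    """Surface-species totals (nM) at in-vivo seeding densities."""
    dens = {"T": 370.0, "tumor": 1e5, "APC": 10.0}
    totals = {}
    for cell, d in dens.items():
        for sp in profiles.species_on(cell):
            totals[sp] = totals.get(sp, 0.0) + surface_concentration(
                profiles.copies(cell, sp, registry), d
            )
    return totals


@pytest.fixture(scope="session")
def invivo_config():
    return default_scenario("invivo")


@pytest.fixture(scope="session")
def control_run(invivo_config):
    """Untreated in-vivo run, shared across tests that need a control arm."""
    from immunoqsp.engine import simulate

    return simulate(invivo_config.control())
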