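"""Synthetic calibration-style datasets for end-to-end pipeline testing.

The generator simulates a scenario at known ("truth") parameters, samples
observations on a schedule, applies multiplicative lognormal noise (tumor
volumes and phospho-signals are positive and right-skewed) and optionally
normalizes traces to their maximum.  The truth record is returned alongside
so parameter-recovery loops (generate -> calibrate -> compare) close.
Nothing here touches the network; fixtures are fully programmatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import simulate, _OBSERVABLES
from .model_config import ScenarioConfig, default_scenario


@dataclass
class FixtureSpec:
    """Recipe for one synthetic dataset.

    ``scenarios`` maps arm name -> ScenarioConfig; ``true_overrides`` maps
    parameter name -> truth value applied to every arm; ``cv`` is the
    lognormal coefficient of variation of the multiplicative noise
    (mean-one, so noise does not bias the level).
    """

    scenarios: Mapping[str, ScenarioConfig]
    observables: Sequence[str] = ("tumor_volume",)
    #: observation times (days); a flat sequence applies to every arm, a
    #: mapping gives each arm its own schedule
    schedule: Sequence[float] | Mapping[str, Sequence[float]] = ()
    true_overrides: Mapping[str, float] = field(default_factory=dict)
    cv: float = 0.2
    normalize: bool = False
    seed: int = 0
    #: fixed per-arm override columns (e.g. a "dose:<drug>" scale), letting
    #: several arms share one scenario structure
    arm_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("noise CV must be >= 0")
        for arm, cfg in self.scenarios.items():
            for t in self.arm_schedule(arm):
                if t < 0 or t > cfg.horizon:
                    raise ValueError(
                        f"{arm}: observation time {t} outside the horizon"
                    )

    def arm_schedule(self, arm: str) -> np.ndarray:
        sched = (
            self.schedule.get(arm, ())
            if isinstance(self.schedule, Mapping)
            else self.schedule
        )
        return np.asarray(list(sched), dtype=float)


def generate_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate at truth, observe on the schedule, add noise.

    Returns ``(observations, truth)`` where observations has columns
    (arm, time, observable, value) and truth records the parameter values
    and the noiseless trajectories used.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.cv**2))
    rows = []
    truth: dict = {"parameters": dict(spec.true_overrides), "noiseless": {}}
    for arm, cfg in spec.scenarios.items():
        schedule = spec.arm_schedule(arm)
        run_cfg = cfg
        if spec.true_overrides:
            run_cfg = ScenarioConfig.from_dict(cfg.to_dict())
            for name, val in spec.true_overrides.items():
                run_cfg.registry.set_value(name, float(val))
        extra = spec.arm_overrides.get(arm)
        overrides = pd.DataFrame({k: [v] for k, v in extra.items()}) if extra else None
        t_eval = np.union1d([0.0, cfg.horizon], schedule)
        res = simulate(run_cfg, overrides, t_eval=t_eval)
        for obs in spec.observables:
            key = _OBSERVABLES[obs]
            clean = np.array([np.interp(t, res.t, res.states[key][0]) for t in schedule])
            if spec.normalize:
                clean = clean / max(clean.max(), 1e-30)
            truth["noiseless"][(arm, obs)] = clean.copy()
            if spec.cv > 0:
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=clean.shape))
                values = clean * noise
            else:
                values = clean
            for t, v in zip(schedule, values):
                rows.append({"arm": arm, "time": t, "observable": obs, "value": v})
    return pd.DataFrame(rows), truth


def tumor_growth_fixture(
    seed: int = 0,
    cv: float = 0.1,
    true_kg: float | None = None,
    true_kkill: float | None = None,
    true_km4: float | None = None,
    dose_mg_per_kg: float = 30.0,
    horizon: float = 12.0,
) -> FixtureSpec:
    """Standard recovery fixture: anti-PD-1 study with three dose arms.

    One scenario structure (weekly anti-PD-1 at ``dose_mg_per_kg``) serves
    three arms through a dose scale: control (0x), a partial-blockade
    mid-dose arm (0.1x) and a near-saturating high-dose arm (1x).  The
    control pins the net growth rate and the saturating arm isolates the
    clearance capacity with the PD-1 brake released.  A fourth arm is a
    T-cell-dense co-culture (cytokine-release-style data): there the PD-1
    complex sits far above its half-effect, so the measured IFN-gamma
    responds steeply to the PD-1 regulatory strength km4, which in-vivo
    volumes constrain only weakly at physiological infiltration.
    """
    from .model_config import DoseRegimen, Treatment, make_mab

    base = default_scenario("invivo", horizon=horizon)
    # noise (>=5% CV) dominates solver error at these tolerances
    base.solver.rtol = 1e-4
    base.solver.atol = 1e-7
    truth = {}
    if true_kg is not None:
        truth["kg_tumor"] = true_kg
    if true_kkill is not None:
        truth["kkill_tumor"] = true_kkill
    if true_km4 is not None:
        truth["km4"] = true_km4
    drug = make_mab("PD-1", base.registry)
    treated = base.with_treatments(
        [Treatment(drug=drug, regimen=DoseRegimen.qw(dose_mg_per_kg, horizon))]
    )
    treated.solver = base.solver
    coculture = default_scenario(
        "invitro_coculture",
        horizon=3.0,
        densities={"T": 5000.0, "tumor": 1.0e5, "APC": 10.0},
    )
    coculture.solver = base.solver
    invivo_times = tuple(np.arange(3.0, horizon + 1e-9, 3.0))
    return FixtureSpec(
        scenarios={
            "control": treated, "mid": treated, "high": treated,
            "coculture": coculture,
        },
        observables=("tumor_volume", "IFNg"),
        schedule={
            "control": invivo_times, "mid": invivo_times, "high": invivo_times,
            "coculture": (0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
        },
        true_overrides=truth,
        cv=cv,
        seed=seed,
        arm_overrides={
            "control": {f"dose:{drug.name}": 0.0},
            "mid": {f"dose:{drug.name}": 0.1},
            "high": {f"dose:{drug.name}": 1.0},
        },
    )
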