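"""Cell-level dynamics: tumor growth/killing and T cell proliferation.

Tumor volume follows first-order (logistic) growth toward a prespecified
maximal volume, with a clearance term driven by a composite Hill drive H
built multiplicatively from T cell activation state, the effector:target
ratio, and IFN-gamma.  Tumor volume is an exact linear map of tumor cell
count (density 1e5 cells/mm^3); immune cells do not contribute to the
measured volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: tumor cells per mm^3; also the in-vivo seeding density
TUMOR_DENSITY = 1e5
T_DENSITY_0 = 370.0
APC_DENSITY_0 = 10.0


@dataclass
class CellPools:
    n_tumor: float
    n_T: float
    n_APC: float


def seed_invivo(v0_mm3: float) -> CellPools:
    """Initial cell pools for a tumor of volume ``v0_mm3``.

    Seeds 1e5 tumor cells, 370 T cells and 10 APCs per mm^3.
    """
    if v0_mm3 <= 0:
        raise ValueError("initial tumor volume must be > 0")
    return CellPools(
        n_tumor=TUMOR_DENSITY * v0_mm3,
        n_T=T_DENSITY_0 * v0_mm3,
        n_APC=APC_DENSITY_0 * v0_mm3,
    )


def tumor_rhs(v, kg, vmax, kkill, hill_drive):
    """dV/dt = kg V (1 - V/Vmax) - kkill V H, logistic growth minus killing."""
    return kg * v * (1.0 - v / vmax) - kkill * v * hill_drive


def logistic_solution(t, v0, kg, vmax):
    """Closed-form drug-free tumor trajectory (oracle for the numeric run)."""
    t = np.asarray(t, dtype=float)
    return vmax / (1.0 + (vmax / v0 - 1.0) * np.exp(-kg * t))


def kill_drive(activation, effector_ratio, ifng, km_act, km_et, km_ifng):
    """Composite kill drive H in [0, 1].

    Multiplicative saturating Hill factors for (i) the T cell activation
    composite, (ii) the effector:target ratio, (iii) IFN-gamma; each factor
    saturates at 1, so H = 0.125 when all three sit at their half-max.
    No T cells or no activation means no killing.
    """
    a = np.asarray(activation, dtype=float)
    r = np.asarray(effector_ratio, dtype=float)
    g = np.asarray(ifng, dtype=float)
    return (a / (a + km_act)) * (r / (r + km_et)) * (g / (g + km_ifng))


def tcell_rhs(n_T, il2, kprolif_basal, kprolif_il2, km_il2, kdeath, n_T_max):
    """IL-2-boosted logistic T cell proliferation minus first-order death."""
    growth = kprolif_basal + kprolif_il2 * il2 / (km_il2 + il2)
    return growth * n_T * (1.0 - n_T / n_T_max) - kdeath * n_T


def percent_killing(n_treated_end, n_control_end):
    """In-vitro cytotoxicity readout: 100 x (1 - treated/control) at assay end."""
    return 100.0 * (1.0 - np.asarray(n_treated_end, dtype=float) / n_control_end)
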