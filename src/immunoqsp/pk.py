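"""Two-compartment antibody pharmacokinetics with repeat IV bolus dosing.

The plasma model is the standard linear central/peripheral system

    dA1/dt = -(CL/Vc) A1 - (Q/Vc) A1 + (Q/Vp) A2        (central amount)
    dA2/dt =  (Q/Vc) A1 - (Q/Vp) A2                      (peripheral amount)

with each bolus adding its dose to the central compartment.  Because the
system is linear, the multi-dose solution is the superposition of shifted
single-dose biexponentials, which is what :func:`simulate_pk` evaluates by
default (a numeric ODE path is kept for cross-validation).  The tumor
concentration is the plasma concentration scaled by a partition
coefficient Kp; drug consumed by target binding in the tumor is not fed
back into the plasma mass balance (the tumor is a sink of negligible
volume), which keeps plasma PK linear.

One shared parameter set serves all antibodies by default — mirroring the
use of a single calibrated mouse IgG profile — and is overridable per drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_config import DoseRegimen, DrugSpec, ParameterRegistry


@dataclass
class PKParams:
    """Mouse antibody PK constants (mL and days); Kp is tumor:plasma."""

    CL: float = 0.2  # mL/day
    Vc: float = 1.0  # mL
    Vp: float = 1.0  # mL
    Q: float = 0.5  # mL/day
    Kp: float = 0.3  # dimensionless, in (0, 1.5]

    def __post_init__(self):
        if min(self.CL, self.Vc, self.Vp, self.Q) < 0 or self.Vc <= 0 or self.Vp <= 0:
            raise ValueError("PK parameters must be positive (CL, Q may be 0)")
        if not (0 < self.Kp <= 1.5):
            raise ValueError("Kp must lie in (0, 1.5]")

    @classmethod
    def from_registry(cls, reg: ParameterRegistry) -> "PKParams":
        return cls(
            CL=reg["CL_pk"], Vc=reg["Vc_pk"], Vp=reg["Vp_pk"],
            Q=reg["Q_pk"], Kp=reg["Kp_tumor"],
        )

    def hybrid_constants(self) -> tuple[float, float, float]:
        """Macro rate constants (alpha, beta) and k21 of the biexponential."""
        k10 = self.CL / self.Vc
        k12 = self.Q / self.Vc
        k21 = self.Q / self.Vp
        s = k10 + k12 + k21
        disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        return alpha, beta, k21


def dose_to_central_concentration(
    regimen: DoseRegimen, drug: DrugSpec, pk: PKParams
) -> float:
    """Initial central concentration (nM) added by one bolus.

    C0 = dose(mg/kg) x bodyweight(kg) / MW(g/mol) / Vc(L) expressed in nM:
    1 mg/kg into a 20 g mouse at MW 1.5e5 and Vc 1 mL gives 133.3 nM.
    """
    if drug.mw <= 0 or pk.Vc <= 0:
        raise ValueError("molecular weight and central volume must be positive")
    mass_mg = regimen.dose_mg_per_kg * regimen.body_weight_g * 1e-3
    nmol = mass_mg * 1e6 / drug.mw
    return nmol / (pk.Vc * 1e-3)


def _single_dose_concentration(t, c0, pk: PKParams):
    """Plasma concentration after one bolus at t=0 (biexponential, exact)."""
    t = np.asarray(t, dtype=float)
    alpha, beta, k21 = pk.hybrid_constants()
    out = np.zeros_like(t)
    pos = t >= 0
    if alpha == beta:  # fully degenerate (CL = Q = 0): mass stays put
        out[pos] = c0 * np.exp(-alpha * t[pos])
        return out
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)
    out[pos] = c0 * (A * np.exp(-alpha * t[pos]) + B * np.exp(-beta * t[pos]))
    return out


def simulate_pk(
    regimen: DoseRegimen,
    pk: PKParams,
    horizon: float,
    t_eval=None,
    drug: DrugSpec | None = None,
    method: str = "analytic",
):
    """Plasma concentration time series (nM) under repeat IV bolus dosing.

    ``method='analytic'`` superposes exact shifted biexponentials;
    ``method='numeric'`` integrates the two-compartment ODE with event
    restarts at dose times (used as a cross-check of the closed form).
    """
    from .model_config import DrugSpec as _DrugSpec

    if drug is None:
        drug = _DrugSpec(name="IgG", modality="mAb",
                         arms=[__default_arm()], mw=1.5e5)
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 200)
    t_eval = np.asarray(t_eval, dtype=float)
    c0 = dose_to_central_concentration(regimen, drug, pk)
    if method == "analytic":
        conc = np.zeros_like(t_eval)
        for td in regimen.times:
            if td <= horizon:
                conc += _single_dose_concentration(t_eval - td, c0, pk)
        return t_eval, conc
    if method == "numeric":
        return t_eval, _simulate_pk_numeric(regimen, pk, c0, t_eval)
    raise ValueError(f"unknown method {method!r}")


def _simulate_pk_numeric(regimen, pk: PKParams, c0, t_eval):
    from scipy.integrate import solve_ivp

    k10, k12, k21 = pk.CL / pk.Vc, pk.Q / pk.Vc, pk.Q / pk.Vp

    def rhs(t, y):
        a1, a2 = y
        return [-(k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    dose_amount = c0 * pk.Vc  # nmol-equivalent units (concentration x volume)
    events = [td for td in regimen.times if td <= t_eval[-1]]
    edges = sorted(set([float(t_eval[0])] + events + [float(t_eval[-1])]))
    y = np.array([0.0, 0.0])
    conc = np.zeros_like(t_eval)
    done = np.zeros_like(t_eval, dtype=bool)
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t0 in events or (t0 == 0.0 and 0.0 in events):
            y = y + np.array([dose_amount, 0.0])
        mask = (t_eval >= t0) & (t_eval <= t1) & ~done
        pts = np.unique(np.concatenate([[t0], t_eval[mask], [t1]]))
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA",
                        t_eval=pts, rtol=1e-10, atol=1e-12)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"PK integration failed: {sol.message}")
        for i in np.nonzero(mask)[0]:
            j = np.searchsorted(sol.t, t_eval[i])
            j = min(j, len(sol.t) - 1)
            conc[i] = sol.y[0][j] / pk.Vc
            done[i] = True
        y = sol.y[:, -1]
    return conc


def tumor_concentration(plasma_series, kp: float):
    """Tumor drug concentration: instantaneous partition C_tumor = Kp * C_plasma."""
    if kp <= 0:
        raise ValueError("Kp must be > 0")
    return kp * np.asarray(plasma_series, dtype=float)


def auc_infinite(regimen: DoseRegimen, drug: DrugSpec, pk: PKParams) -> float:
    """Analytic AUC(0, inf) = total dose / CL, in nM*day."""
    c0 = dose_to_central_concentration(regimen, drug, pk)
    total_amount = c0 * pk.Vc * len(regimen.times)
    return total_amount / pk.CL


def __default_arm():
    from .model_config import DrugArm

    return DrugArm(target="PD-1", mode="blocking", kon=8.64, koff=86.4)
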