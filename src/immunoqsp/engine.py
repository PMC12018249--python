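"""Scenario assembly, in-vitro/in-vivo simulation, endpoints, and calibration.

A :class:`ModelSystem` couples the modules into one ODE system per scenario:

* binding (checkpoint ligation + drug-target complexes) is treated as a
  rapid equilibrium relative to the hour-to-day-scale signaling, cell and
  PK dynamics: inside the right-hand side, complex levels are obtained from
  the algebraic equilibrium solver given the current species totals.  Mass
  conservation of every receptor/ligand/drug pool is then exact by
  construction, and the stiff binding kinetics drop out of the integrator.
* antibody plasma PK is linear two-compartment with bolus dosing, so the
  intratumoral concentration is evaluated in closed form (superposed
  biexponentials scaled by the partition coefficient) and enters the
  system as a forcing function; integration restarts at dose times.
* the dynamic state per subject is: TCR responsiveness, five signaling
  hubs, IL-2, IFN-gamma, tumor size, T cell count, and surface CTLA4
  (the only activation-induced checkpoint).

The same signaling and cell-interaction terms serve all three modes
(in-vitro stimulation, in-vitro co-culture, in-vivo); the modes differ only
in compartment bookkeeping and drug exposure (fixed bath vs PK-driven).

Everything is vectorized over a batch of parameter sets (one per virtual
mouse), which is what makes population-scale screens tractable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cells, signaling
from .binding import (
    EquilibriumProblem,
    build_checkpoint_binding,
    build_drug_binding,
)
from .model_config import (
    DoseRegimen,
    DrugSpec,
    ParameterRegistry,
    ScenarioConfig,
    Treatment,
    NM_PER_COPY_DENSITY,
)
from .optimize import PatternSearchResult, pattern_search
from .pk import PKParams, _single_dose_concentration, dose_to_central_concentration

STATE_NAMES = (
    "R_tcr", "ZAP70", "PI3K", "AKT", "ERK", "NFkB",
    "IL2", "IFNg", "tumor", "N_T", "CTLA4_pc",
)
_STATE_SCALE = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1e3, 1e6, 1e3])


def config_hash(config: ScenarioConfig, overrides: pd.DataFrame | None = None) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if overrides is not None:
        text += overrides.to_csv()
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Trajectories plus endpoint summaries for one (possibly batched) run."""

    t: np.ndarray  # (nt,)
    states: dict  # name -> (B, nt)
    config: ScenarioConfig
    provenance: dict
    endpoints: dict = field(default_factory=dict)

    @property
    def batch_size(self) -> int:
        return next(iter(self.states.values())).shape[0]

    def series(self, name: str, subject: int = 0) -> np.ndarray:
        return self.states[name][subject]

    def at_day(self, name: str, day: float) -> np.ndarray:
        """Linear interpolation of a state at a given day, per subject."""
        vals = self.states[name]
        return np.array([np.interp(day, self.t, row) for row in vals])

    def to_frame(self, scenario_id: str = "run") -> pd.DataFrame:
        """Tidy long-format export (time, species, value, subject, scenario)."""
        rows = []
        for name, mat in self.states.items():
            for b in range(mat.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "time": self.t,
                            "species": name,
                            "value": mat[b],
                            "subject": b,
                            "scenario": scenario_id,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


class ModelSystem:
    """Fully-assembled ODE system for one scenario (batched over subjects)."""

    def __init__(self, config: ScenarioConfig, overrides: pd.DataFrame | None = None):
        self.config = config
        self.overrides = overrides
        self.B = 1 if overrides is None else len(overrides)
        self._build_parameters()
        self._build_network()
        self._build_exposure()

    # -- parameters --------------------------------------------------------
    def _p(self, name: str):
        return self._params[name]

    def _build_parameters(self):
        reg = self.config.registry
        self._params: dict[str, np.ndarray | float] = {
            name: float(reg[name]) for name in reg
        }
        self._v0 = np.full(self.B, float(self.config.v0_mm3))
        if self.overrides is not None:
            for col in self.overrides.columns:
                if col == "v0_mm3":
                    self._v0 = self.overrides[col].to_numpy(dtype=float)
                elif col.startswith(("bath:", "dose:")):
                    continue
                elif col in self._params:
                    self._params[col] = self.overrides[col].to_numpy(dtype=float)
                else:
                    raise KeyError(f"override column {col!r} is not a model parameter")

    # -- binding network ---------------------------------------------------
    def _build_network(self):
        cfg = self.config
        net = build_checkpoint_binding(cfg.profiles, cfg.registry)
        for tr in cfg.treatments:
            net = build_drug_binding(tr.drug, net)
        self.network = net
        self.problem = EquilibriumProblem.from_network(net)
        base = self.problem.base
        self._base_index = {n: i for i, n in enumerate(base)}
        cx = {n: i for i, n in enumerate(self.problem.complexes)}
        self._cx = cx
        # static copies/cell tensor (B, cell type, base species); the CTLA4
        # slot on T cells is refreshed from the dynamic state at each call
        prof = cfg.profiles
        self._cells_order = ("T", "tumor", "APC")
        copies = np.zeros((self.B, len(self._cells_order), len(base)))
        self._ctla4_pos = None
        for si, name in enumerate(base):
            for ci_cell, cell in enumerate(self._cells_order):
                mapping = prof.expression.get(cell, {})
                if name in mapping:
                    if cell == "T" and name == "CTLA4":
                        self._ctla4_pos = (ci_cell, si)
                    copies[:, ci_cell, si] = np.broadcast_to(
                        np.asarray(self._p(mapping[name])), (self.B,)
                    )
        self._copies = copies
        # agonist-arm contributions: target -> [(complex index, weight key)]
        w_tri = float(cfg.registry["trimer_weight"])
        self._agonist_pools: dict[str, list[tuple[int, float]]] = {
            "TCR": [], "CD28": [], "OX40": [], "4-1BB": [],
        }
        for tr in cfg.treatments:
            d = tr.drug
            for arm in d.arms:
                if arm.mode != "agonist" or arm.target not in self._agonist_pools:
                    continue
                self._agonist_pools[arm.target].append(
                    (cx[f"{d.name}:{arm.target}"], 1.0)
                )
                if d.modality == "BsAb":
                    a1, a2 = d.arms
                    tname = f"{a1.target}:{d.name}:{a2.target}"
                    self._agonist_pools[arm.target].append((cx[tname], w_tri))

    # -- drug exposure -----------------------------------------------------
    def _build_exposure(self):
        cfg = self.config
        self._drug_conc: list[tuple[str, Callable[[float], np.ndarray]]] = []
        events: set[float] = set()
        pk = PKParams.from_registry(cfg.registry)
        self.pk = pk
        for i, tr in enumerate(cfg.treatments):
            if cfg.mode == "invivo":
                if tr.regimen is None:
                    raise ValueError(f"{tr.drug.name}: in-vivo treatment needs a regimen")
                c0 = dose_to_central_concentration(tr.regimen, tr.drug, pk)
                times = tuple(t for t in tr.regimen.times if t <= cfg.horizon)
                events.update(times)
                kp = pk.Kp
                scale = np.ones(self.B)
                if self.overrides is not None:
                    col = f"dose:{tr.drug.name}"
                    if col in self.overrides.columns:
                        scale = self.overrides[col].to_numpy(dtype=float)

                def conc(t, _c0=c0, _times=times, _kp=kp, _s=scale):
                    c = 0.0
                    for td in _times:
                        if t >= td:
                            c += _single_dose_concentration(
                                np.array([t - td]), _c0, pk
                            )[0]
                    return _s * (_kp * c)

                self._drug_conc.append((tr.drug.name, conc))
            else:
                bath = np.full(self.B, 0.0 if tr.bath_nM is None else float(tr.bath_nM))
                if self.overrides is not None:
                    col = f"bath:{tr.drug.name}"
                    if col in self.overrides.columns:
                        bath = self.overrides[col].to_numpy(dtype=float)
                self._drug_conc.append(
                    (tr.drug.name, lambda t, _b=bath: _b)
                )
        self.dose_events = sorted(e for e in events if 0.0 < e < cfg.horizon)

    # -- initial state -----------------------------------------------------
    def initial_state(self) -> np.ndarray:
        cfg = self.config
        B = self.B
        y0 = np.zeros((B, len(STATE_NAMES)))
        y0[:, 0] = 1.0  # fully responsive TCR pool
        ct0 = np.broadcast_to(np.asarray(self._p("CTLA4_per_cell")), (B,))
        y0[:, 10] = ct0
        if cfg.mode == "invivo":
            y0[:, 8] = self._v0
            t_dens = np.broadcast_to(np.asarray(self._p("T_density_0")), (B,))
            y0[:, 9] = t_dens * self._v0
        else:
            y0[:, 8] = float(cfg.densities.get("tumor", 0.0))
            y0[:, 9] = float(cfg.densities.get("T", 0.0))
        return y0

    # -- right-hand side ---------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        cfg = self.config
        B = self.B
        p = self._p
        Y = np.maximum(y.reshape(B, len(STATE_NAMES)), 0.0)
        R = np.minimum(Y[:, 0], 1.0)
        hubs = {h: np.minimum(Y[:, 1 + i], 1.0) for i, h in enumerate(signaling.HUBS)}
        il2, ifng = Y[:, 6], Y[:, 7]
        tum, n_T, ct_pc = Y[:, 8], Y[:, 9], Y[:, 10]

        # cell densities (cells/mm^3) and effector:target bookkeeping
        dens = np.empty((B, 3))
        if cfg.mode == "invivo":
            # density bookkeeping floors the volume at 0.5 mm^3: below that
            # the lesion is effectively eradicated and per-mm^3 densities of
            # the residual infiltrate are no longer meaningful
            V = np.maximum(tum, 0.5)
            dens[:, 0] = n_T / V
            dens[:, 1] = cells.TUMOR_DENSITY
            dens[:, 2] = np.broadcast_to(np.asarray(p("APC_density_0")), (B,)) * self._v0 / V
            n_tumor = cells.TUMOR_DENSITY * V
        else:
            dens[:, 0] = n_T
            dens[:, 1] = tum
            dens[:, 2] = float(cfg.densities.get("APC", 0.0))
            n_tumor = tum

        # species totals (nM) and binding equilibrium
        if self._ctla4_pos is not None:
            ci_cell, si = self._ctla4_pos
            self._copies[:, ci_cell, si] = ct_pc
        totals = (
            (self._copies * dens[:, :, None]).sum(axis=1) * NM_PER_COPY_DENSITY
        )
        for name, conc in self._drug_conc:
            totals[:, self._base_index[name]] = conc(t)
        _, cx, _ = self.problem.solve(totals, warm_start=True)

        def raw_pool(key):
            if key in ("4-1BB*", "OX40*", "TCR*", "CD28*"):
                nat = {
                    "4-1BB*": "4-1BB:4-1BBL", "OX40*": "OX40:OX40L",
                    "TCR*": "TCR:MHC", "CD28*": "CD28:CD8086",
                }[key]
                pool = cx[:, self._cx[nat]].copy()
                for ci, w in self._agonist_pools[key[:-1]]:
                    pool = pool + w * cx[:, ci]
                return pool
            return cx[:, self._cx[key]]

        # Hub regulation reads bulk complex concentrations (the km4..km12
        # half-effects are in nM): expanding T cells competing for shared
        # ligand pools is the model's density feedback.
        level = raw_pool

        # TCR input: engaged fraction (per-cell by construction) x
        # responsive pool x LAG3 gate
        tcr_tot = np.maximum(totals[:, self._base_index["TCR"]], 1e-30)
        occ_tcr = np.clip(raw_pool("TCR*") / tcr_tot, 0.0, 1.0)
        h = float(p("hill_checkpoint"))
        gate = signaling.lag3_tcr_gate(level("LAG3:MHCII"), p("km_LAG3"), h)
        s_tcr = occ_tcr * (R if cfg.options["desensitization"] else 1.0) * gate

        # checkpoint modulation factors per hub
        def inh(key, km):
            return signaling.checkpoint_modulation_factor(level(key), p(km), h, "inhibitory")

        def stim(key, km, emax):
            return signaling.checkpoint_modulation_factor(
                level(key), p(km), h, "stimulatory", p(emax)
            )

        mods = {
            "ZAP70": inh("PD-1:PD-L1", "km4") * inh("TIGIT:CD155", "km6")
            * inh("CTLA4:CD8086", "km12"),
            "PI3K": inh("PD-1:PD-L1", "km5")
            * stim("CD28*", "km_CD28_PI3K", "emax_CD28_PI3K"),
            "AKT": stim("4-1BB*", "km9", "emax_41BB_AKT")
            * stim("OX40*", "km10", "emax_OX40_AKT"),
            "ERK": stim("4-1BB*", "km8", "emax_41BB_ERK"),
            "NFkB": inh("TIGIT:CD155", "km7") * stim("OX40*", "km11", "emax_OX40_NFkB"),
        }
        # shared downstream capacity saturates: the composite boost a hub can
        # receive from convergent stimulatory inputs is bounded (also keeps
        # the activation flux from becoming artificially stiff when two
        # agonist arms multiply on one hub)
        mods = {h: np.minimum(m, 10.0) for h, m in mods.items()}
        upstream = {
            "ZAP70": s_tcr, "PI3K": s_tcr,
            "AKT": hubs["PI3K"], "ERK": hubs["ZAP70"], "NFkB": hubs["ZAP70"],
        }

        dY = np.zeros_like(Y)
        dY[:, 0] = signaling.tcr_desensitization_rhs(
            R, occ_tcr * gate, p("kdes_TCR"), p("krec_TCR")
        )
        for i, hname in enumerate(signaling.HUBS):
            dY[:, 1 + i] = signaling.hub_activation_rhs(
                hubs[hname], p(f"kf_{hname}"), p(f"kr_{hname}"),
                upstream[hname], mods[hname],
            )
        g = signaling.cytokine_drive(hubs["NFkB"], hubs["ERK"], hubs["AKT"])
        dY[:, 6] = signaling.cytokine_rhs(il2, p("kf_IL2"), p("kdeg_IL2"), g)
        dY[:, 7] = signaling.cytokine_rhs(ifng, p("kf_IFNg"), p("kdeg_IFNg"), g)

        # tumor and T cells
        if cfg.options["kill_effector_basis"] == "ratio":
            eff = np.where(n_tumor > 0, n_T / np.maximum(n_tumor, 1e-30), 0.0)
        else:
            eff = n_T
        H = cells.kill_drive(
            g, eff, ifng, p("km_act_kill"), p("km_ET_kill"), p("km_IFNg_kill")
        )
        if cfg.mode == "invivo":
            dY[:, 8] = cells.tumor_rhs(tum, p("kg_tumor"), p("Vmax_tumor"), p("kkill_tumor"), H)
            # the T cell carrying capacity shares the eradication volume
            # floor; otherwise the logistic brake diverges as V -> 0
            nt_max = np.asarray(p("NTmax_density")) * np.maximum(tum, 0.5)
        else:
            cap = p("tumor_capacity_invitro")
            dY[:, 8] = cells.tumor_rhs(tum, p("kg_tumor"), cap, p("kkill_tumor"), H)
            nt_max = np.broadcast_to(np.asarray(p("NTmax_density")), (B,))
        dY[:, 9] = cells.tcell_rhs(
            n_T, il2, p("kprolif_T_basal"), p("kprolif_T_IL2"),
            p("km_IL2_T"), p("kdeath_T"), nt_max,
        )
        # bounded contraction: after tumor collapse the infiltrate shrinks
        # at a finite rate instead of an unbounded logistic overshoot
        dY[:, 9] = np.maximum(dY[:, 9], -10.0 * n_T)
        if "CTLA4" in cfg.profiles.induced:
            dY[:, 10] = signaling.ctla4_induction_rhs(
                ct_pc, hubs["NFkB"], p("CTLA4_per_cell"),
                p("CTLA4_ceiling_per_cell"), p("k_CTLA4_induction"),
            )
        # freeze depleted pools (no negative excursions)
        dY[:, 8] = np.where((tum <= 0) & (dY[:, 8] < 0), 0.0, dY[:, 8])
        dY[:, 9] = np.where((n_T <= 0) & (dY[:, 9] < 0), 0.0, dY[:, 9])
        return dY.ravel()


def assemble_system(
    config: ScenarioConfig, overrides: pd.DataFrame | None = None
) -> ModelSystem:
    """Build the complete ODE system for a scenario.

    With no treatments this is the disease-progression model; in-vitro modes
    skip PK and use fixed bath drug concentrations.  The state layout is
    deterministic for a given config.
    """
    return ModelSystem(config, overrides)


# --------------------------------------------------------------------------
# simulation drivers
# --------------------------------------------------------------------------

def simulate(
    config: ScenarioConfig,
    overrides: pd.DataFrame | None = None,
    t_eval: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate a scenario and return trajectories for every subject."""
    from scipy.integrate import solve_ivp

    system = assemble_system(config, overrides)
    y0 = system.initial_state()
    B, n = y0.shape
    if t_eval is None:
        t_eval = np.linspace(0.0, config.horizon, config.n_out)
    t_eval = np.asarray(t_eval, dtype=float)
    atol = np.tile(config.solver.atol * _STATE_SCALE, B)
    edges = [0.0] + [e for e in system.dose_events] + [config.horizon]
    edges = sorted(set(edges))
    out = np.zeros((len(t_eval), B, n))
    y = y0.ravel().copy()
    filled = np.zeros(len(t_eval), dtype=bool)
    if t_eval[0] == 0.0:
        out[0] = y0
        filled[0] = True
    for t0, t1 in zip(edges[:-1], edges[1:]):
        mask = (t_eval > t0) & (t_eval <= t1) & ~filled
        pts = np.unique(np.concatenate([[t0], t_eval[mask], [t1]]))
        sol = solve_ivp(
            system.rhs, (t0, t1), y,
            method=config.solver.method,
            t_eval=pts,
            rtol=config.solver.rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"scenario integration failed on [{t0}, {t1}]: {sol.message}")
        for i in np.nonzero(mask)[0]:
            j = int(np.searchsorted(sol.t, t_eval[i]))
            j = min(j, len(sol.t) - 1)
            out[i] = sol.y[:, j].reshape(B, n)
            filled[i] = True
        y = sol.y[:, -1]
    states = {
        name: np.ascontiguousarray(out[:, :, k].T) for k, name in enumerate(STATE_NAMES)
    }
    prov = {
        "config_hash": config_hash(config, overrides),
        "seed": config.seed,
        "solver": config.solver.to_dict(),
    }
    return SimulationResult(t=t_eval, states=states, config=config, provenance=prov)


def simulate_invivo(
    config: ScenarioConfig, overrides: pd.DataFrame | None = None
) -> SimulationResult:
    """Tumor-bearing mouse simulation; the control arm is the same config
    with the treatment list emptied."""
    if config.mode != "invivo":
        raise ValueError("config.mode must be 'invivo'")
    return simulate(config, overrides)


def simulate_invitro_stimulation(
    config: ScenarioConfig, overrides: pd.DataFrame | None = None
) -> SimulationResult:
    """Antibody-stimulation / co-culture signaling time courses.

    Adds max-normalized hub and cytokine traces (``norm_<name>``), mirroring
    how phospho-protein readouts are reported relative to their maxima.
    """
    if config.mode != "invitro_stimulation":
        raise ValueError("config.mode must be 'invitro_stimulation'")
    res = simulate(config, overrides)
    for name in signaling.HUBS + ("IL2", "IFNg"):
        mat = res.states[name]
        peak = np.maximum(mat.max(axis=1, keepdims=True), 1e-30)
        res.states[f"norm_{name}"] = mat / peak
    return res


def simulate_invitro_cytotoxicity(
    config: ScenarioConfig,
    drug: DrugSpec,
    dose_grid_nM: Sequence[float],
) -> pd.DataFrame:
    """Dose-response of % tumor killing and cytokine fold-change.

    Simulates the co-culture at each bath concentration (plus the untreated
    control) out to the assay endpoint and reports
    ``%killing = 100 (1 - N_treated/N_control)`` and end-point IL-2/IFN-g
    fold changes over control.
    """
    if config.mode != "invitro_coculture":
        raise ValueError("config.mode must be 'invitro_coculture'")
    doses = np.asarray(list(dose_grid_nM), dtype=float)
    cfg = config.with_treatments([Treatment(drug=drug, bath_nM=0.0)])
    cfg.horizon = float(config.options["assay_endpoint_days"])
    all_doses = np.concatenate([[0.0], doses])
    overrides = pd.DataFrame({f"bath:{drug.name}": all_doses})
    res = simulate(cfg, overrides)
    n_end = res.states["tumor"][:, -1]
    il2_end = res.states["IL2"][:, -1]
    ifng_end = res.states["IFNg"][:, -1]
    ctrl = n_end[0]
    return pd.DataFrame(
        {
            "dose_nM": doses,
            "pct_killing": cells.percent_killing(n_end[1:], ctrl),
            "il2_fold": il2_end[1:] / max(il2_end[0], 1e-30),
            "ifng_fold": ifng_end[1:] / max(ifng_end[0], 1e-30),
        }
    )


def compute_tgi(
    treated: SimulationResult,
    control: SimulationResult,
    day: float | None = None,
) -> np.ndarray:
    """Tumor growth inhibition (%) of treated vs control at a reference day.

    Default convention: ``TGI = 100 (1 - V_t/V_c)`` evaluated at ``day``
    (end of study if omitted).  The ``tgi_convention: delta`` option uses
    the growth-delta form ``100 (1 - dV_t/dV_c)`` instead.
    """
    if len(treated.t) != len(control.t) or not np.allclose(treated.t, control.t):
        raise ValueError("treated and control runs must share the time grid")
    day = float(treated.t[-1]) if day is None else float(day)
    v_t = treated.at_day("tumor", day)
    v_c = control.at_day("tumor", day)
    if np.any(v_c <= 0):
        raise ValueError("control tumor volume must be positive at the evaluation day")
    if treated.config.options.get("tgi_convention", "ratio") == "delta":
        v0_t = treated.states["tumor"][:, 0]
        v0_c = control.states["tumor"][:, 0]
        return 100.0 * (1.0 - (v_t - v0_t) / (v_c - v0_c))
    return 100.0 * (1.0 - v_t / v_c)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

_OBSERVABLES = {
    "tumor_volume": "tumor", "tumor_count": "tumor", "N_T": "N_T",
    "IL2": "IL2", "IFNg": "IFNg",
    **{h: h for h in signaling.HUBS},
}


def calibrate_parameters(
    scenarios: Mapping[str, ScenarioConfig],
    data: pd.DataFrame,
    free: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    x0: Sequence[float] | None = None,
    max_evals: int = 2000,
    seed: int = 0,
    arm_overrides: Mapping[str, Mapping[str, float]] | None = None,
    log_scale: bool = True,
) -> tuple[ParameterRegistry, PatternSearchResult]:
    """Fit registry parameters to time-course data by pattern search.

    ``data`` columns: arm (a key of ``scenarios``), time, observable, value.
    The objective is the weighted sum of squared residuals, each observable
    trace weighted by 1/max(|value|) within its arm so different scales
    contribute comparably.  Derivative-free pattern search (coordinate
    polling, contraction 0.5, expansion 2.0) runs within the given bounds,
    which must lie inside each parameter's registry range; by default the
    search works in log coordinates, the natural scale for rate and
    affinity constants.  Deterministic given the start point.

    ``arm_overrides`` attaches fixed per-arm override columns (for example a
    ``dose:<drug>`` scale factor); arms that share the same ScenarioConfig
    object are simulated together as one batch, as is each poll set.
    """
    free = list(free)
    any_cfg = next(iter(scenarios.values()))
    for name in free:
        lo, hi = bounds[name]
        e = any_cfg.registry.entry(name)
        if lo < e.lower or hi > e.upper:
            raise ValueError(f"bounds for {name} exceed registry range")
    lower = np.array([bounds[n][0] for n in free])
    upper = np.array([bounds[n][1] for n in free])
    arm_overrides = dict(arm_overrides or {})
    weights = {
        key: 1.0 / max(np.abs(grp["value"]).max(), 1e-30)
        for key, grp in data.groupby(["arm", "observable"])
    }
    # arms sharing one ScenarioConfig object run as a single batched call
    groups: dict[int, list[str]] = {}
    cfg_of: dict[int, ScenarioConfig] = {}
    for arm, cfg in scenarios.items():
        groups.setdefault(id(cfg), []).append(arm)
        cfg_of[id(cfg)] = cfg

    def objective_batch(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        m = len(X)
        sse = np.zeros(m)
        for key, arms in groups.items():
            cfg = cfg_of[key]
            arms_used = [a for a in arms if not data[data["arm"] == a].empty]
            if not arms_used:
                continue
            frames = []
            for a in arms_used:
                f = pd.DataFrame({n: X[:, j] for j, n in enumerate(free)})
                for col, val in arm_overrides.get(a, {}).items():
                    f[col] = val
                frames.append(f)
            ov = pd.concat(frames, ignore_index=True).fillna(0.0)
            sub_all = data[data["arm"].isin(arms_used)]
            t_need = np.unique(sub_all["time"].to_numpy(dtype=float))
            res = simulate(cfg, ov, t_eval=np.union1d([0.0], t_need))
            for ai, a in enumerate(arms_used):
                sub = data[data["arm"] == a]
                rows = slice(ai * m, (ai + 1) * m)
                for obs, grp in sub.groupby("observable"):
                    mat = res.states[_OBSERVABLES[obs]][rows]
                    tt = grp["time"].to_numpy(dtype=float)
                    vv = grp["value"].to_numpy(dtype=float)
                    pred = np.vstack([np.interp(tt, res.t, row) for row in mat])
                    sse += weights[(a, obs)] ** 2 * (
                        (pred - vv[None, :]) ** 2
                    ).sum(axis=1)
        return sse

    if log_scale:
        s_lower, s_upper = np.log(lower), np.log(upper)
        unmap = np.exp
    else:
        s_lower, s_upper = lower, upper
        unmap = np.asarray
    start = (
        0.5 * (s_lower + s_upper)
        if x0 is None
        else (np.log(x0) if log_scale else np.asarray(x0, dtype=float))
    )
    result = pattern_search(
        fun=lambda z: float(objective_batch(unmap(z)[None, :])[0]),
        x0=start, lower=s_lower, upper=s_upper,
        fun_batch=lambda Z: objective_batch(unmap(Z)),
        max_evals=max_evals,
    )
    result.x = unmap(result.x)
    fitted = any_cfg.registry.copy()
    for name, val in zip(free, result.x):
        fitted.set_value(name, float(val))
    return fitted, result
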