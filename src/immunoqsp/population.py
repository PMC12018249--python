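"""Virtual mouse populations, target-pair screens, regimens, Sobol GSA, statistics.

A virtual population is a Latin-hypercube sample of physiological parameter
ranges (initial tumor volume, tumor growth/clearance rates, IL-2 production,
checkpoint expression levels, initial T cell density), one vector per
virtual mouse, reproducible from its seed.  Every analysis here simulates
the whole population as one batched ODE run per treatment arm, with the
matched untreated arm providing per-mouse TGI.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult, compute_tgi, simulate
from .model_config import (
    DoseRegimen,
    DrugSpec,
    ParameterRegistry,
    ScenarioConfig,
    Treatment,
    default_scenario,
    make_bsab,
    make_mab,
    TARGETABLE_CHECKPOINTS,
)

__all__ = [
    "PopulationSpec",
    "VirtualPopulation",
    "default_population_spec",
    "sample_population",
    "apply_subgroup",
    "population_tgi",
    "screen_bsab_pairs",
    "dose_grid_combo",
    "compare_regimens",
    "triple_combination",
    "response_depth_bins",
    "wilcoxon_ranksum",
    "sobol_total_order",
    "SobolResult",
    "ScreenResult",
]


# --------------------------------------------------------------------------
# population sampling
# --------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Sampling ranges: name -> (lower, upper, scale) with scale log|linear."""

    ranges: dict
    n: int = 100

    def __post_init__(self):
        for name, (lo, hi, scale) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"{name}: lower {lo} > upper {hi}")
            if scale not in ("log", "linear"):
                raise ValueError(f"{name}: unknown scale {scale!r}")
            if scale == "log" and lo <= 0:
                raise ValueError(f"{name}: log-scale range must be positive")


@dataclass
class VirtualPopulation:
    """Sampled parameter vectors, one row per virtual mouse."""

    params: pd.DataFrame
    seed: int
    spec: PopulationSpec
    label: str = "base"

    @property
    def n(self) -> int:
        return len(self.params)


def default_population_spec(
    registry: ParameterRegistry | None = None, n: int = 100
) -> PopulationSpec:
    """Shipped sampling ranges: 3-fold log-uniform around the default for
    rates and expression levels, +/-50% uniform for initial volume and
    T cell seeding density (clipped to each entry's declared bounds)."""
    from .model_config import default_registry

    reg = registry if registry is not None else default_registry()
    ranges: dict = {"v0_mm3": (50.0, 150.0, "linear")}

    def logrange(name, fold=3.0):
        e = reg.entry(name)
        return (max(e.value / fold, e.lower), min(e.value * fold, e.upper), "log")

    for name in ("kg_tumor", "kkill_tumor", "kf_IL2"):
        ranges[name] = logrange(name)
    for ckpt in ("PD-1", "TIGIT", "LAG3", "CTLA4", "OX40", "4-1BB"):
        ranges[f"{ckpt}_per_cell"] = logrange(f"{ckpt}_per_cell")
    for name in ("PD-L1_per_cell", "CD155_per_cell"):
        ranges[name] = logrange(name)
    e = reg.entry("T_density_0")
    ranges["T_density_0"] = (max(e.value * 0.5, e.lower), min(e.value * 1.5, e.upper), "linear")
    return PopulationSpec(ranges=ranges, n=n)


def _transform_unit(u: np.ndarray, lo: float, hi: float, scale: str) -> np.ndarray:
    if scale == "log":
        return lo * np.exp(u * np.log(hi / lo)) if hi > lo else np.full_like(u, lo)
    return lo + u * (hi - lo)


def sample_population(
    spec: PopulationSpec | None = None, seed: int = 0, label: str = "base"
) -> VirtualPopulation:
    """Latin-hypercube draw of a virtual population; deterministic per seed."""
    from scipy.stats import qmc

    spec = spec if spec is not None else default_population_spec()
    names = list(spec.ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    U = sampler.random(spec.n)
    cols = {}
    for j, name in enumerate(names):
        lo, hi, scale = spec.ranges[name]
        cols[name] = _transform_unit(U[:, j], lo, hi, scale)
    return VirtualPopulation(
        params=pd.DataFrame(cols), seed=seed, spec=spec, label=label
    )


def apply_subgroup(
    pop: VirtualPopulation,
    checkpoint: str,
    level: str = "low",
    decile: float = 0.1,
) -> VirtualPopulation:
    """Checkpoint-low subgroup: resample that checkpoint's T cell expression
    from the lower decile of its declared range; other parameters untouched."""
    if level != "low":
        raise ValueError("only the 'low' expression subgroup is defined")
    name = f"{checkpoint}_per_cell"
    if name not in pop.params.columns:
        raise KeyError(f"unknown or unsampled checkpoint {checkpoint!r}")
    lo, hi, scale = pop.spec.ranges[name]
    rng = np.random.default_rng([pop.seed, zlib.crc32(name.encode())])
    u = rng.random(pop.n) * decile
    params = pop.params.copy()
    params[name] = _transform_unit(u, lo, hi, scale)
    return VirtualPopulation(
        params=params, seed=pop.seed, spec=pop.spec,
        label=f"{checkpoint} (Low)",
    )


# --------------------------------------------------------------------------
# population TGI machinery
# --------------------------------------------------------------------------

def population_tgi(
    pop: VirtualPopulation,
    treatments: Sequence[Treatment],
    base_config: ScenarioConfig | None = None,
    day: float | None = None,
    control: SimulationResult | None = None,
) -> tuple[np.ndarray, SimulationResult]:
    """Per-mouse TGI for a treatment arm against the matched untreated arm.

    The control run can be passed in and reused across arms that share the
    population and base scenario.
    """
    cfg = base_config if base_config is not None else default_scenario("invivo")
    if control is None:
        control = simulate(cfg.control(), pop.params)
    treated = simulate(cfg.with_treatments(list(treatments)), pop.params)
    return compute_tgi(treated, control, day), control


# --------------------------------------------------------------------------
# bispecific target-pair screen
# --------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Mean population TGI for every unordered checkpoint pair per dose."""

    table: pd.DataFrame  # columns: target_a, target_b, dose_mg_per_kg, mean_tgi
    doses: tuple
    n_mice: int

    def matrix(self, dose: float) -> pd.DataFrame:
        """Symmetric checkpoint x checkpoint TGI matrix at one dose level."""
        sub = self.table[self.table["dose_mg_per_kg"] == dose]
        mat = pd.DataFrame(
            np.nan, index=list(TARGETABLE_CHECKPOINTS), columns=list(TARGETABLE_CHECKPOINTS)
        )
        for _, row in sub.iterrows():
            mat.loc[row["target_a"], row["target_b"]] = row["mean_tgi"]
            mat.loc[row["target_b"], row["target_a"]] = row["mean_tgi"]
        return mat


def screen_bsab_pairs(
    pop: VirtualPopulation,
    dose_levels: Sequence[float] = (1.0, 10.0),
    base_config: ScenarioConfig | None = None,
    day: float | None = None,
) -> ScreenResult:
    """TGI screen of all 21 bispecific combinations of the 7 checkpoints.

    Arm modes are auto-assigned (blocking for inhibitory targets, agonist
    for 4-1BB/OX40); each virtual BsAb is dosed once weekly at each level
    and scored by mean population TGI against the shared untreated arm.
    """
    cfg = base_config if base_config is not None else default_scenario("invivo")
    control = simulate(cfg.control(), pop.params)
    rows = []
    for a, b in itertools.combinations(TARGETABLE_CHECKPOINTS, 2):
        drug = make_bsab(a, b, cfg.registry)
        for dose in dose_levels:
            regimen = DoseRegimen.qw(dose, cfg.horizon)
            tgi, _ = population_tgi(
                pop, [Treatment(drug=drug, regimen=regimen)], cfg, day, control
            )
            rows.append(
                {
                    "target_a": a,
                    "target_b": b,
                    "dose_mg_per_kg": dose,
                    "mean_tgi": float(np.mean(tgi)),
                }
            )
    return ScreenResult(
        table=pd.DataFrame(rows), doses=tuple(dose_levels), n_mice=pop.n
    )


def dose_grid_combo(
    drug_a: DrugSpec,
    drug_b: DrugSpec,
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    pop: VirtualPopulation,
    base_config: ScenarioConfig | None = None,
    day: float | None = None,
) -> pd.DataFrame:
    """Mean population TGI surface over a two-drug dose grid.

    Zero-dose rows/columns reduce to the respective monotherapy curves, and
    the (0, 0) cell is the control (TGI 0 by definition).
    """
    cfg = base_config if base_config is not None else default_scenario("invivo")
    control = simulate(cfg.control(), pop.params)
    rows = []
    for da in doses_a:
        for db in doses_b:
            treatments = []
            if da > 0:
                treatments.append(
                    Treatment(drug=drug_a, regimen=DoseRegimen.qw(da, cfg.horizon))
                )
            if db > 0:
                treatments.append(
                    Treatment(drug=drug_b, regimen=DoseRegimen.qw(db, cfg.horizon))
                )
            if treatments:
                tgi, _ = population_tgi(pop, treatments, cfg, day, control)
                mean_tgi = float(np.mean(tgi))
            else:
                mean_tgi = 0.0
            rows.append(
                {"dose_a": da, "dose_b": db, "mean_tgi": mean_tgi}
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# dosing regimens and response depth
# --------------------------------------------------------------------------

def response_depth_bins(tgi: np.ndarray) -> dict:
    """Percent of mice with TGI >= 40, 20 < TGI < 40, and TGI <= 20."""
    tgi = np.asarray(tgi, dtype=float)
    n = len(tgi)
    return {
        "deep (>=40%)": 100.0 * np.sum(tgi >= 40.0) / n,
        "partial (20-40%)": 100.0 * np.sum((tgi > 20.0) & (tgi < 40.0)) / n,
        "low (<=20%)": 100.0 * np.sum(tgi <= 20.0) / n,
    }


@dataclass
class RegimenComparison:
    tgi: pd.DataFrame  # one column per regimen, one row per mouse
    pvalues: pd.DataFrame  # pairwise two-sided rank-sum p (raw + Holm)
    bins: pd.DataFrame  # response-depth bins per regimen (percent)


def compare_regimens(
    drug: DrugSpec,
    regimens: Mapping[str, DoseRegimen],
    pop: VirtualPopulation,
    base_config: ScenarioConfig | None = None,
    day: float | None = None,
) -> RegimenComparison:
    """Per-mouse TGI distributions under alternative dosing regimens.

    Reports pairwise two-sided Wilcoxon rank-sum p-values (raw, plus a
    Holm-adjusted column) and the response-depth binning of each arm.
    """
    cfg = base_config if base_config is not None else default_scenario("invivo")
    control = simulate(cfg.control(), pop.params)
    tgis = {}
    for name, regimen in regimens.items():
        tgi, _ = population_tgi(
            pop, [Treatment(drug=drug, regimen=regimen)], cfg, day, control
        )
        tgis[name] = tgi
    tgi_df = pd.DataFrame(tgis)
    pairs = list(itertools.combinations(tgis, 2))
    raw = [wilcoxon_ranksum(tgis[a], tgis[b])[1] for a, b in pairs]
    holm = _holm(raw)
    pvals = pd.DataFrame(
        {
            "regimen_a": [a for a, _ in pairs],
            "regimen_b": [b for _, b in pairs],
            "p_value": raw,
            "p_holm": holm,
        }
    )
    bins = pd.DataFrame({name: response_depth_bins(t) for name, t in tgis.items()})
    return RegimenComparison(tgi=tgi_df, pvalues=pvals, bins=bins)


def _holm(pvals: Sequence[float]) -> list[float]:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


# --------------------------------------------------------------------------
# triple (BsAb + mAb) combinations
# --------------------------------------------------------------------------

def triple_combination(
    bsab: DrugSpec,
    mab: DrugSpec,
    pops: Mapping[str, VirtualPopulation],
    base_config: ScenarioConfig | None = None,
    dose_bsab: float = 1.0,
    dose_mab: float = 1.0,
    day: float | None = None,
) -> pd.DataFrame:
    """Mean TGI of BsAb alone vs BsAb + mAb across population subgroups.

    The three targets must be distinct (a true triple-checkpoint strategy);
    a zero mAb dose reduces exactly to the BsAb-alone arm.
    """
    if set(bsab.targets) & set(mab.targets):
        raise ValueError("BsAb and mAb targets overlap; three distinct targets required")
    cfg = base_config if base_config is not None else default_scenario("invivo")
    rows = []
    for name, pop in pops.items():
        control = simulate(cfg.control(), pop.params)
        solo = [Treatment(drug=bsab, regimen=DoseRegimen.qw(dose_bsab, cfg.horizon))]
        tgi_solo, _ = population_tgi(pop, solo, cfg, day, control)
        combo = list(solo)
        if dose_mab > 0:
            combo.append(
                Treatment(drug=mab, regimen=DoseRegimen.qw(dose_mab, cfg.horizon))
            )
        tgi_combo, _ = population_tgi(pop, combo, cfg, day, control)
        rows.append(
            {
                "subgroup": name,
                "bsab_alone": float(np.mean(tgi_solo)),
                "bsab_plus_mab": float(np.mean(tgi_combo)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def wilcoxon_ranksum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum of the first sample.  Small
    untied samples (n <= 10 each) use the exact null distribution;
    otherwise the tie-corrected normal approximation applies.  Identical
    constant samples give p = 1 by convention.
    """
    from scipy.stats import mannwhitneyu, rankdata

    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    W = float(ranks[: len(a)].sum())
    if np.ptp(pooled) == 0:
        return W, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return W, float(min(res.pvalue, 1.0))


# --------------------------------------------------------------------------
# Sobol global sensitivity analysis
# --------------------------------------------------------------------------

@dataclass
class SobolResult:
    names: list
    first_order: np.ndarray
    total_order: np.ndarray
    first_order_ci: np.ndarray  # (2, d) low/high
    total_order_ci: np.ndarray
    output: str
    n: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "S1": self.first_order,
                "S1_lo": self.first_order_ci[0],
                "S1_hi": self.first_order_ci[1],
                "ST": self.total_order,
                "ST_lo": self.total_order_ci[0],
                "ST_hi": self.total_order_ci[1],
            }
        ).sort_values("ST", ascending=False, ignore_index=True)

    def ranked(self) -> list:
        return list(self.to_frame()["parameter"])


def sobol_total_order(
    ranges: Mapping[str, tuple],
    output: Callable[[pd.DataFrame], np.ndarray],
    n: int = 1024,
    seed: int = 0,
    n_boot: int = 100,
    output_name: str = "output",
) -> SobolResult:
    """First- and total-order Sobol indices of ``output`` over ``ranges``.

    ``ranges`` maps parameter name -> (lower, upper, scale); ``output``
    maps a parameter DataFrame (one row per sample) to one value per row.
    Saltelli-type estimators over a base sample of size ``n`` (a power of
    two), with bootstrap confidence intervals.  Failed evaluations
    (non-finite outputs) are imputed with the mean of the finite ones and
    counted in ``n_failed``.
    """
    from scipy import stats

    if n & (n - 1):
        raise ValueError("n must be a power of 2")
    names = list(ranges)
    n_failed = 0

    def func(x: np.ndarray) -> np.ndarray:
        nonlocal n_failed
        cols = {
            name: _transform_unit(x[j], *ranges[name])
            for j, name in enumerate(names)
        }
        vals = np.asarray(output(pd.DataFrame(cols)), dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            n_failed += int(bad.sum())
            vals[bad] = np.mean(vals[~bad]) if (~bad).any() else 0.0
        return vals

    dists = [stats.uniform(loc=0.0, scale=1.0) for _ in names]
    res = stats.sobol_indices(
        func=func, n=n, dists=dists, rng=np.random.default_rng(seed)
    )
    boot = res.bootstrap(confidence_level=0.95, n_resamples=n_boot)
    return SobolResult(
        names=names,
        first_order=np.asarray(res.first_order),
        total_order=np.asarray(res.total_order),
        first_order_ci=np.vstack(
            [boot.first_order.confidence_interval.low,
             boot.first_order.confidence_interval.high]
        ),
        total_order_ci=np.vstack(
            [boot.total_order.confidence_interval.low,
             boot.total_order.confidence_interval.high]
        ),
        output=output_name,
        n=n,
        n_failed=n_failed,
    )


def invivo_day25_output(
    base_config: ScenarioConfig | None = None, day: float = 25.0
) -> Callable[[pd.DataFrame], np.ndarray]:
    """Output functional for GSA: untreated in-vivo tumor volume at day 25,
    starting from a 100 mm^3 tumor."""
    cfg = (base_config if base_config is not None else default_scenario("invivo")).control()

    def output(params: pd.DataFrame) -> np.ndarray:
        res = simulate(cfg, params, t_eval=np.array([0.0, day]))
        return res.states["tumor"][:, -1]

    return output
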