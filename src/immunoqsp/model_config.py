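"""Parameter registry, drug/regimen/scenario schemas and shipped defaults.

Everything downstream (binding network assembly, signaling, tumor dynamics,
PK, population sampling) reads named constants from a :class:`ParameterRegistry`
and surface-expression layouts from :class:`CheckpointProfiles`.  The shipped
defaults live in ``configs/default/`` inside the package and are fully
config-overridable; analyses are pure functions of the configuration so a
user can substitute their own calibrated values.

Units convention (used consistently across in-vitro and in-vivo modes):
concentrations in nM, time in days, volumes in mm^3 (tumor) or mL (PK).
Surface species are converted to nM as copies/cell x cell density / Avogadro.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

#: nM per (copies/cell x cells/mm^3):  1e6 mm^3/L * 1e9 nmol/mol / N_A
NM_PER_COPY_DENSITY = 1e15 / 6.02214076e23

#: The seven checkpoints a therapeutic antibody arm may target.
TARGETABLE_CHECKPOINTS = ("PD-1", "PD-L1", "CTLA4", "LAG3", "TIGIT", "OX40", "4-1BB")

#: Receptors whose engagement stimulates (rather than inhibits) T cells.
STIMULATORY_RECEPTORS = ("OX40", "4-1BB", "TCR", "CD28")

CELL_TYPES = ("T", "tumor", "APC")

#: Physiological carrier restriction for each surface species.
ALLOWED_CELLS = {
    "TCR": {"T"},
    "PD-1": {"T"},
    "TIGIT": {"T"},
    "LAG3": {"T"},
    "CTLA4": {"T"},
    "CD28": {"T"},
    "OX40": {"T"},
    "4-1BB": {"T"},
    "PD-L1": {"tumor", "APC"},
    "CD155": {"tumor", "APC"},
    "MHC": {"tumor", "APC"},
    "MHCII": {"tumor", "APC"},
    "CD8086": {"APC"},
    "OX40L": {"APC"},
    "4-1BBL": {"APC"},
}

ROLES = ("binding", "signaling", "cell", "pk", "expression")

#: Registry names that must exist for the model to be assembled.
REQUIRED_PARAMETERS = (
    ("kf_IL2",)
    + tuple(f"km{i}" for i in range(4, 13))
    + tuple(f"{x}_per_cell" for x in TARGETABLE_CHECKPOINTS)
)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

@dataclass
class ParameterEntry:
    """One named, unit-annotated, range-bounded model constant."""

    value: float
    units: str = ""
    lower: float = 0.0
    upper: float = math.inf
    role: str = "signaling"
    source: str = ""

    def to_dict(self) -> dict:
        return {
            "value": float(self.value),
            "units": self.units,
            "lower": float(self.lower),
            "upper": float(self.upper),
            "role": self.role,
            "source": self.source,
        }


@dataclass
class Violation:
    """A single validation failure; violations are data, not exceptions."""

    name: str
    rule: str
    message: str


class ParameterRegistry:
    """Mapping of unique parameter names to :class:`ParameterEntry`.

    Supports dict-style value access (``reg["kg_tumor"]`` returns the float
    value) plus ``entry(name)`` for the full record.
    """

    def __init__(self, entries: Mapping[str, ParameterEntry] | None = None):
        self.entries: dict[str, ParameterEntry] = dict(entries or {})

    def __getitem__(self, name: str) -> float:
        return self.entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterRegistry):
            return NotImplemented
        return {k: v.to_dict() for k, v in self.entries.items()} == {
            k: v.to_dict() for k, v in other.entries.items()
        }

    def entry(self, name: str) -> ParameterEntry:
        return self.entries[name]

    def get(self, name: str, default: float | None = None) -> float | None:
        e = self.entries.get(name)
        return default if e is None else e.value

    def set_value(self, name: str, value: float) -> None:
        """Override a value, enforcing the declared range."""
        e = self.entries[name]
        if not (e.lower <= value <= e.upper):
            raise ValueError(
                f"{name}={value} outside declared range [{e.lower}, {e.upper}]"
            )
        e.value = float(value)

    def add(self, name: str, value: float, **kwargs) -> None:
        if name in self.entries:
            raise ValueError(f"duplicate parameter name {name!r}")
        self.entries[name] = ParameterEntry(value=float(value), **kwargs)

    def copy(self) -> "ParameterRegistry":
        return ParameterRegistry(copy.deepcopy(self.entries))

    def to_dict(self) -> dict:
        return {name: e.to_dict() for name, e in sorted(self.entries.items())}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterRegistry":
        entries = {}
        for name, rec in d.items():
            if isinstance(rec, Mapping):
                entries[name] = ParameterEntry(
                    value=float(rec["value"]),
                    units=str(rec.get("units", "")),
                    lower=float(rec.get("lower", 0.0)),
                    upper=float(rec.get("upper", math.inf)),
                    role=str(rec.get("role", "signaling")),
                    source=str(rec.get("source", "")),
                )
            else:  # bare number: value-only override form
                entries[name] = ParameterEntry(value=float(rec))
        return cls(entries)


# --------------------------------------------------------------------------
# checkpoint profiles
# --------------------------------------------------------------------------

@dataclass
class CheckpointProfiles:
    """Surface copies/cell per cell type, resolved from the registry.

    ``expression[cell][species]`` is the registry parameter name holding the
    copies/cell for that species on that cell.  ``induced`` lists species
    whose surface level is activation-induced (only CTLA4 in the default
    model; all other checkpoints are constant).
    """

    expression: dict[str, dict[str, str]]
    induced: tuple[str, ...] = ("CTLA4",)

    def copies(self, cell: str, species: str, registry: ParameterRegistry) -> float:
        return registry[self.expression[cell][species]]

    def species_on(self, cell: str) -> tuple[str, ...]:
        return tuple(self.expression.get(cell, {}))

    def carriers(self, species: str) -> tuple[str, ...]:
        return tuple(c for c, m in self.expression.items() if species in m)

    def to_dict(self) -> dict:
        return {
            "profiles": {
                cell: {
                    sp: (
                        {"parameter": par, "induced": True}
                        if sp in self.induced
                        else {"parameter": par}
                    )
                    for sp, par in mapping.items()
                }
                for cell, mapping in self.expression.items()
            }
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CheckpointProfiles":
        profiles = d["profiles"] if "profiles" in d else d
        expression: dict[str, dict[str, str]] = {}
        induced: list[str] = []
        for cell, mapping in profiles.items():
            expression[cell] = {}
            for sp, rec in mapping.items():
                expression[cell][sp] = str(rec["parameter"])
                if rec.get("induced"):
                    induced.append(sp)
        return cls(expression=expression, induced=tuple(sorted(set(induced))))


# --------------------------------------------------------------------------
# drugs and regimens
# --------------------------------------------------------------------------

@dataclass
class DrugArm:
    """One antigen-binding arm of an antibody."""

    target: str
    mode: str  # "blocking" | "agonist"
    kon: float  # 1/(nM*day)
    koff: float  # 1/day

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass
class DrugSpec:
    """A monoclonal (one arm) or bispecific (two arms) antibody."""

    name: str
    modality: str  # "mAb" | "BsAb"
    arms: list[DrugArm]
    mw: float = 1.5e5  # g/mol
    alpha: float = 10.0  # BsAb trimer crosslink (avidity) factor

    def __post_init__(self):
        if self.modality == "mAb" and len(self.arms) != 1:
            raise ValueError("a mAb has exactly one arm")
        if self.modality == "BsAb":
            if len(self.arms) != 2:
                raise ValueError("a BsAb has exactly two arms")
            if self.arms[0].target == self.arms[1].target:
                raise ValueError("BsAb arms must target two distinct checkpoints")
        if self.alpha <= 0:
            raise ValueError("crosslink factor alpha must be > 0")
        for arm in self.arms:
            if arm.kon <= 0 or arm.koff <= 0:
                raise ValueError(f"{self.name}: kon/koff must be positive")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(a.target for a in self.arms)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "modality": self.modality,
            "arms": [asdict(a) for a in self.arms],
            "mw": self.mw,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DrugSpec":
        return cls(
            name=d["name"],
            modality=d["modality"],
            arms=[DrugArm(**a) for a in d["arms"]],
            mw=float(d.get("mw", 1.5e5)),
            alpha=float(d.get("alpha", 10.0)),
        )


def _default_koff(reg: ParameterRegistry, target: str) -> float:
    """Per-target default arm off-rate, falling back to the generic IgG value."""
    v = reg.get(f"koff_drug_{target}")
    return v if v is not None else reg["koff_drug_default"]


def default_arm_mode(target: str) -> str:
    """Blocking for inhibitory targets, agonist for costimulatory receptors."""
    return "agonist" if target in STIMULATORY_RECEPTORS else "blocking"


def make_mab(
    target: str,
    registry: ParameterRegistry | None = None,
    mode: str | None = None,
    kon: float | None = None,
    koff: float | None = None,
    name: str | None = None,
) -> DrugSpec:
    """Construct a monoclonal antibody against one checkpoint with default kinetics."""
    reg = registry if registry is not None else default_registry()
    arm = DrugArm(
        target=target,
        mode=mode or default_arm_mode(target),
        kon=kon if kon is not None else reg["kon_drug_default"],
        koff=koff if koff is not None else _default_koff(reg, target),
    )
    return DrugSpec(
        name=name or f"anti-{target}",
        modality="mAb",
        arms=[arm],
        mw=reg["MW_antibody"],
        alpha=reg["alpha_crosslink"],
    )


def make_bsab(
    target_a: str,
    target_b: str,
    registry: ParameterRegistry | None = None,
    name: str | None = None,
) -> DrugSpec:
    """Construct a bispecific antibody; arm modes auto-assigned by target class."""
    reg = registry if registry is not None else default_registry()
    arms = [
        DrugArm(
            target=t,
            mode=default_arm_mode(t),
            kon=reg["kon_drug_default"],
            koff=_default_koff(reg, t),
        )
        for t in (target_a, target_b)
    ]
    return DrugSpec(
        name=name or f"anti-{target_a}/{target_b}",
        modality="BsAb",
        arms=arms,
        mw=reg["MW_antibody"],
        alpha=reg["alpha_crosslink"],
    )


@dataclass
class DoseRegimen:
    """IV bolus dosing: dose in mg per kg body weight at listed times (days)."""

    dose_mg_per_kg: float
    times: tuple[float, ...]
    route: str = "iv_bolus"
    body_weight_g: float = 20.0

    def __post_init__(self):
        self.dose_mg_per_kg = float(self.dose_mg_per_kg)
        self.body_weight_g = float(self.body_weight_g)
        if self.dose_mg_per_kg < 0:
            raise ValueError("dose must be >= 0")
        t = tuple(float(x) for x in self.times)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("dosing times must be strictly increasing")
        self.times = t

    @classmethod
    def qw(cls, dose: float, horizon: float, start: float = 0.0, **kw) -> "DoseRegimen":
        """Once-weekly dosing over the study horizon."""
        times = tuple(t for t in _arange(start, horizon, 7.0))
        return cls(dose_mg_per_kg=dose, times=times, **kw)

    @classmethod
    def biw(cls, dose: float, horizon: float, start: float = 0.0, **kw) -> "DoseRegimen":
        """Twice-weekly (every 3.5 d) dosing over the study horizon."""
        times = tuple(t for t in _arange(start, horizon, 3.5))
        return cls(dose_mg_per_kg=dose, times=times, **kw)

    @property
    def total_dose(self) -> float:
        return self.dose_mg_per_kg * len(self.times)

    def to_dict(self) -> dict:
        return {
            "dose_mg_per_kg": self.dose_mg_per_kg,
            "times": list(self.times),
            "route": self.route,
            "body_weight_g": self.body_weight_g,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DoseRegimen":
        return cls(
            dose_mg_per_kg=float(d["dose_mg_per_kg"]),
            times=tuple(float(t) for t in d["times"]),
            route=str(d.get("route", "iv_bolus")),
            body_weight_g=float(d.get("body_weight_g", 20.0)),
        )


def _arange(start: float, stop: float, step: float) -> list[float]:
    out, t = [], start
    while t < stop - 1e-9:
        out.append(round(t, 9))
        t += step
    return out


@dataclass
class Treatment:
    """One drug plus either an in-vivo regimen or an in-vitro bath concentration."""

    drug: DrugSpec
    regimen: DoseRegimen | None = None
    bath_nM: float | None = None

    def to_dict(self) -> dict:
        return {
            "drug": self.drug.to_dict(),
            "regimen": None if self.regimen is None else self.regimen.to_dict(),
            "bath_nM": self.bath_nM,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Treatment":
        return cls(
            drug=DrugSpec.from_dict(d["drug"]),
            regimen=None if d.get("regimen") is None else DoseRegimen.from_dict(d["regimen"]),
            bath_nM=None if d.get("bath_nM") is None else float(d["bath_nM"]),
        )


# --------------------------------------------------------------------------
# scenario configuration
# --------------------------------------------------------------------------

MODES = ("invitro_stimulation", "invitro_coculture", "invivo")


@dataclass
class SolverOptions:
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "RK45"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScenarioConfig:
    """One executable experiment: compartments, cells, drugs, regimen, horizon."""

    mode: str = "invivo"
    horizon: float = 25.0  # days
    n_out: int = 126  # output grid points (includes t=0)
    v0_mm3: float = 100.0  # in-vivo initial tumor volume
    densities: dict = field(default_factory=dict)  # in-vitro cells/mm^3 per cell type
    treatments: list = field(default_factory=list)
    registry: ParameterRegistry = field(default_factory=lambda: default_registry())
    profiles: CheckpointProfiles = field(default_factory=lambda: default_profiles())
    solver: SolverOptions = field(default_factory=SolverOptions)
    seed: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.mode == "invivo" and self.v0_mm3 <= 0:
            raise ValueError("initial tumor volume must be > 0")
        defaults = {
            "desensitization": True,
            "tgi_convention": "ratio",  # or "delta"
            "kill_effector_basis": "ratio",  # or "count"
            "assay_endpoint_days": 3.0,  # in-vitro cytotoxicity readout (72 h)
            "partition_delay": 0.0,  # 1/day; 0 = instantaneous tumor partition
        }
        self.options = {**defaults, **self.options}
        if not self.densities and self.mode != "invivo":
            # effective contact densities (cells/mm^3): co-pelleted cells
            # interact at tissue-like density, not bulk-medium dilution, so
            # the default co-culture mirrors the in-vivo seeding densities
            # and surface-ligand pools sit at the same nM operating point
            self.densities = (
                {"T": 370.0, "tumor": 0.0, "APC": 0.0}
                if self.mode == "invitro_stimulation"
                else {"T": 370.0, "tumor": 1.0e5, "APC": 10.0}
            )

    def with_treatments(self, treatments: Sequence[Treatment]) -> "ScenarioConfig":
        out = copy.deepcopy(self)
        out.treatments = list(treatments)
        return out

    def control(self) -> "ScenarioConfig":
        """The matched untreated arm (same config, no drugs)."""
        return self.with_treatments([])

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "horizon": self.horizon,
            "n_out": self.n_out,
            "v0_mm3": self.v0_mm3,
            "densities": dict(self.densities),
            "treatments": [t.to_dict() for t in self.treatments],
            "registry": self.registry.to_dict(),
            "profiles": self.profiles.to_dict(),
            "solver": self.solver.to_dict(),
            "seed": self.seed,
            "options": dict(self.options),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        reg = default_registry()
        if "registry" in d and d["registry"]:
            overrides = ParameterRegistry.from_dict(d["registry"])
            for name, e in overrides.entries.items():
                if name in reg and isinstance(d["registry"][name], (int, float)):
                    reg.set_value(name, e.value)  # bare-number override
                else:
                    reg.entries[name] = e
        profiles = (
            CheckpointProfiles.from_dict(d["profiles"])
            if d.get("profiles")
            else default_profiles()
        )
        return cls(
            mode=d.get("mode", "invivo"),
            horizon=float(d.get("horizon", 25.0)),
            n_out=int(d.get("n_out", 126)),
            v0_mm3=float(d.get("v0_mm3", 100.0)),
            densities=dict(d.get("densities", {})),
            treatments=[Treatment.from_dict(t) for t in d.get("treatments", [])],
            registry=reg,
            profiles=profiles,
            solver=SolverOptions(**d.get("solver", {})),
            seed=int(d.get("seed", 0)),
            options=dict(d.get("options", {})),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScenarioConfig):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# --------------------------------------------------------------------------
# shipped defaults and file IO
# --------------------------------------------------------------------------

def _read_packaged_yaml(relpath: str) -> dict:
    ref = importlib.resources.files("immunoqsp").joinpath(f"configs/{relpath}")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def default_registry() -> ParameterRegistry:
    """The shipped curated parameterization (see each entry's ``source`` note)."""
    doc = _read_packaged_yaml("default/parameters.yaml")
    return ParameterRegistry.from_dict(doc["entries"])


def default_profiles() -> CheckpointProfiles:
    doc = _read_packaged_yaml("default/checkpoints.yaml")
    return CheckpointProfiles.from_dict(doc)


def default_model() -> tuple[ParameterRegistry, CheckpointProfiles]:
    """Complete validated default parameterization for every scenario mode."""
    reg, prof = default_registry(), default_profiles()
    violations = validate_parameters(reg, prof)
    if violations:  # pragma: no cover - defaults are validated in the test suite
        raise RuntimeError(f"shipped defaults failed validation: {violations}")
    return reg, prof


def default_scenario(mode: str = "invivo", **kwargs) -> ScenarioConfig:
    """Shipped default scenario for a mode, with keyword overrides."""
    reg, prof = default_model()
    return ScenarioConfig(mode=mode, registry=reg, profiles=prof, **kwargs)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario from YAML (JSON is a YAML subset and parses too)."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValueError(f"{path}: not a mapping at top level")
    cfg = ScenarioConfig.from_dict(doc)
    violations = validate_parameters(cfg.registry, cfg.profiles)
    if violations:
        lines = "; ".join(f"{v.name}: {v.message}" for v in violations)
        raise ValueError(f"{path}: invalid configuration ({lines})")
    return cfg


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a fully-resolved scenario; ``load(save(x)) == x`` round-trips."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_parameters(
    reg: ParameterRegistry,
    profiles: CheckpointProfiles | None = None,
) -> list[Violation]:
    """Check registry (and optionally profile) invariants.

    Returns an empty list iff everything holds; each violation names the
    offending entry and the rule it breaks.
    """
    out: list[Violation] = []
    for name, e in reg.entries.items():
        if not (e.lower <= e.value <= e.upper):
            out.append(
                Violation(name, "range", f"value {e.value} outside [{e.lower}, {e.upper}]")
            )
        if e.value < 0:
            out.append(Violation(name, "nonnegative", f"value {e.value} is negative"))
        if e.role not in ROLES:
            out.append(Violation(name, "role", f"unknown role {e.role!r}"))
    for name in REQUIRED_PARAMETERS:
        if name not in reg:
            out.append(Violation(name, "required", "required parameter missing"))
    if profiles is not None:
        for cell, mapping in profiles.expression.items():
            if cell not in CELL_TYPES:
                out.append(Violation(cell, "cell_type", f"unknown cell type {cell!r}"))
                continue
            for sp, par in mapping.items():
                allowed = ALLOWED_CELLS.get(sp)
                if allowed is not None and cell not in allowed:
                    out.append(
                        Violation(
                            sp,
                            "cell_restriction",
                            f"{sp} is not expressed on {cell} cells "
                            f"(allowed: {sorted(allowed)})",
                        )
                    )
                if par not in reg:
                    out.append(
                        Violation(par, "required", f"profile references missing entry {par!r}")
                    )
                elif reg[par] < 0:
                    out.append(Violation(par, "nonnegative", "surface copies must be >= 0"))
        for sp in profiles.induced:
            if sp != "CTLA4":
                out.append(
                    Violation(
                        sp,
                        "induced",
                        "only CTLA4 may be activation-induced in the default model",
                    )
                )
    return out
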