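"""Mass-action binding networks for checkpoint ligation and antibody binding.

Two layers live here:

* a literal :class:`ReactionNetwork` of reversible 1:1 mass-action reactions
  (checkpoint-ligand pairs, mAb dimers, BsAb dimer->trimer), integrable as a
  kinetic ODE system for oracle cross-checks; and
* a fast algebraic equilibrium solver (:class:`EquilibriumProblem`) that
  computes the unique steady state of a closed network from species totals,
  exploiting conservation laws and decomposition into independent clusters.

The simulation engine treats binding as rapid equilibrium relative to the
day-scale cell and PK dynamics and calls the algebraic solver inside the ODE
right-hand side; the kinetic layer remains available and the two are held to
agree in the test suite.

Bispecific antibodies first form dimers (drug bound to either target alone)
and then bridge into trimers; the trimer-forming on-rate carries the
crosslink (avidity) factor alpha on BOTH association paths, which preserves
thermodynamic cycle consistency by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model_config import (
    CheckpointProfiles,
    DrugSpec,
    ParameterRegistry,
    NM_PER_COPY_DENSITY,
)

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "MissingSpeciesError",
    "equilibrium_bimolecular",
    "build_checkpoint_binding",
    "build_drug_binding",
    "steady_state_network",
    "ctla4_competition_relief",
    "EquilibriumProblem",
    "surface_concentration",
    "LIGATION_PAIRS",
]

#: nM floor standing in for a truly absent species in the log-domain solver.
_TOTAL_FLOOR = 1e-30


class MissingSpeciesError(KeyError):
    """A reaction references a species absent from the network/profiles."""


def surface_concentration(copies_per_cell: float, density_cells_per_mm3) -> float:
    """Convert surface copies/cell at a cell density to a nM pool."""
    return copies_per_cell * density_cells_per_mm3 * NM_PER_COPY_DENSITY


# --------------------------------------------------------------------------
# network data model
# --------------------------------------------------------------------------

@dataclass
class Species:
    name: str
    carrier: str | None = None  # cell type for surface species, None for soluble
    total: float = 0.0  # nM; conserved quantity for base species
    role: str = "neutral"  # inhibitory | stimulatory | neutral (complexes)
    constituents: tuple[str, ...] = ()  # empty for base species


@dataclass
class Reaction:
    reactants: tuple[str, str]
    product: str
    kon: float  # 1/(nM*day)
    koff: float  # 1/day

    def __post_init__(self):
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError(f"kon/koff must be positive for {self.product}")

    @property
    def keq(self) -> float:
        """Association equilibrium constant kon/koff (1/nM)."""
        return self.kon / self.koff


_LIGATION_ROLES = {
    "PD-1:PD-L1": "inhibitory",
    "TIGIT:CD155": "inhibitory",
    "CTLA4:CD8086": "inhibitory",
    "LAG3:MHCII": "inhibitory",
    "CD28:CD8086": "stimulatory",
    "OX40:OX40L": "stimulatory",
    "4-1BB:4-1BBL": "stimulatory",
    "TCR:MHC": "stimulatory",
}

#: physiological checkpoint-ligand pairs and their kinetic registry keys
LIGATION_PAIRS = (
    ("TCR", "MHC", "TCR_MHC"),
    ("LAG3", "MHCII", "LAG3_MHCII"),
    ("PD-1", "PD-L1", "PD1_PDL1"),
    ("TIGIT", "CD155", "TIGIT_CD155"),
    ("CD28", "CD8086", "CD28_CD8086"),
    ("CTLA4", "CD8086", "CTLA4_CD8086"),
    ("OX40", "OX40L", "OX40_OX40L"),
    ("4-1BB", "4-1BBL", "41BB_41BBL"),
)


class ReactionNetwork:
    """Species plus reversible 1:1 mass-action binding reactions."""

    def __init__(self):
        self.species: dict[str, Species] = {}
        self.reactions: list[Reaction] = []

    # -- construction ------------------------------------------------------
    def add_species(self, sp: Species) -> None:
        if sp.name in self.species:
            raise ValueError(f"duplicate species {sp.name!r}")
        self.species[sp.name] = sp

    def add_reaction(self, rxn: Reaction) -> None:
        for r in rxn.reactants:
            if r not in self.species:
                raise MissingSpeciesError(r)
        if rxn.product not in self.species:
            a, b = rxn.reactants
            cons = self.composition_of(a) + self.composition_of(b)
            self.add_species(
                Species(name=rxn.product, constituents=tuple(sorted(cons)))
            )
        self.reactions.append(rxn)

    def copy(self) -> "ReactionNetwork":
        out = ReactionNetwork()
        for sp in self.species.values():
            out.add_species(Species(**sp.__dict__))
        out.reactions = [Reaction(**r.__dict__) for r in self.reactions]
        return out

    # -- structure ---------------------------------------------------------
    @property
    def base_species(self) -> list[str]:
        products = {r.product for r in self.reactions}
        return [n for n in self.species if n not in products]

    @property
    def complex_species(self) -> list[str]:
        products = {r.product for r in self.reactions}
        return [n for n in self.species if n in products]

    def composition_of(self, name: str) -> tuple[str, ...]:
        """Base-species multiset making up a species (itself if base)."""
        sp = self.species[name]
        return sp.constituents if sp.constituents else (name,)

    def set_totals(self, totals: Mapping[str, float]) -> None:
        for name, tot in totals.items():
            self.species[name].total = float(tot)

    def totals(self) -> dict[str, float]:
        return {n: self.species[n].total for n in self.base_species}

    # -- kinetic (oracle) layer -------------------------------------------
    def _index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.species)}

    def mass_action_rhs(self, y: np.ndarray) -> np.ndarray:
        """d[concentrations]/dt over all species, mass-action kinetics."""
        idx = self._index()
        dy = np.zeros_like(y)
        for rxn in self.reactions:
            a, b = (idx[r] for r in rxn.reactants)
            p = idx[rxn.product]
            flux = rxn.kon * y[a] * y[b] - rxn.koff * y[p]
            dy[a] -= flux
            dy[b] -= flux
            dy[p] += flux
        return dy

    def initial_state(self, totals: Mapping[str, float] | None = None) -> np.ndarray:
        """All mass free (complexes empty), from stored or supplied totals."""
        if totals is not None:
            self.set_totals(totals)
        y0 = np.zeros(len(self.species))
        idx = self._index()
        for n in self.base_species:
            y0[idx[n]] = self.species[n].total
        return y0

    def simulate_kinetics(
        self,
        t_end: float,
        totals: Mapping[str, float] | None = None,
        n_out: int = 50,
        rtol: float = 1e-9,
        atol: float = 1e-12,
    ):
        """Integrate the kinetic ODEs (oracle for the equilibrium solver)."""
        from scipy.integrate import solve_ivp

        y0 = self.initial_state(totals)
        sol = solve_ivp(
            lambda t, y: self.mass_action_rhs(y),
            (0.0, t_end),
            y0,
            method="LSODA",
            t_eval=np.linspace(0.0, t_end, n_out),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"kinetic integration failed: {sol.message}")
        return sol.t, {n: sol.y[i] for i, n in enumerate(self.species)}

    def conserved_totals(self, y: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Total of each base species summed over every complex containing it."""
        out: dict[str, np.ndarray] = {}
        for base in self.base_species:
            tot = np.asarray(y[base], dtype=float).copy()
            for cname in self.complex_species:
                mult = self.composition_of(cname).count(base)
                if mult:
                    tot = tot + mult * np.asarray(y[cname], dtype=float)
            out[base] = tot
        return out

    # -- export ------------------------------------------------------------
    def to_table(self):
        """Reaction list as a tidy DataFrame (reactants, product, kon, koff)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "reactant_1": r.reactants[0],
                    "reactant_2": r.reactants[1],
                    "product": r.product,
                    "kon_per_nM_day": r.kon,
                    "koff_per_day": r.koff,
                    "Kd_nM": r.koff / r.kon,
                }
                for r in self.reactions
            ]
        )

    def summary(self) -> str:
        lines = [f"ReactionNetwork: {len(self.species)} species, {len(self.reactions)} reactions"]
        for r in self.reactions:
            lines.append(
                f"  {r.reactants[0]} + {r.reactants[1]} <-> {r.product}"
                f"  (Kd = {r.koff / r.kon:.3g} nM)"
            )
        return "\n".join(lines)

    def equilibrium_problem(self) -> "EquilibriumProblem":
        return EquilibriumProblem.from_network(self)


# --------------------------------------------------------------------------
# analytic oracle: single reversible pair
# --------------------------------------------------------------------------

def equilibrium_bimolecular(rtot: float, ltot: float, kd: float) -> float:
    """Bound complex at equilibrium for one reversible pair R + L <-> B.

    Returns the unique physical root of
    ``B^2 - (Rtot + Ltot + Kd) B + Rtot Ltot = 0`` with
    ``0 <= B <= min(Rtot, Ltot)``; evaluated in the numerically stable
    product form.  ``Kd = 0`` is the tight-binding limit ``B = min(R, L)``.
    """
    rtot = np.asarray(rtot, dtype=float)
    ltot = np.asarray(ltot, dtype=float)
    if np.any(rtot < 0) or np.any(ltot < 0) or np.any(np.asarray(kd) < 0):
        raise ValueError("totals and Kd must be non-negative")
    if np.ndim(kd) == 0 and kd == 0:
        out = np.minimum(rtot, ltot)
        return float(out) if out.ndim == 0 else out
    s = rtot + ltot + kd
    disc = np.sqrt(np.maximum(s * s - 4.0 * rtot * ltot, 0.0))
    # stable form: 2ab / (s + sqrt(s^2 - 4ab)) avoids cancellation
    denom = s + disc
    out = np.where(denom > 0, 2.0 * rtot * ltot / np.where(denom > 0, denom, 1.0), 0.0)
    out = np.where(np.asarray(kd) == 0, np.minimum(rtot, ltot), out)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# network builders
# --------------------------------------------------------------------------

def build_checkpoint_binding(
    profiles: CheckpointProfiles,
    registry: ParameterRegistry,
) -> ReactionNetwork:
    """Reversible ligation reactions for every physiological checkpoint pair.

    CD80/86 appears as a reactant in two reactions (CD28 and CTLA4 arms),
    encoding the competition through the shared pool.  Species totals are
    left at 0 here; scenarios fill them in from copies/cell and cell
    densities at simulation time.
    """
    net = ReactionNetwork()
    for cell in profiles.expression:
        for sp in profiles.species_on(cell):
            if sp not in net.species:
                net.add_species(Species(name=sp, carrier=cell))
    for a, b, key in LIGATION_PAIRS:
        for sp in (a, b):
            if sp not in net.species:
                raise MissingSpeciesError(
                    f"profiles lack required partner species {sp!r} for pair {a}-{b}"
                )
        cname = f"{a}:{b}"
        net.add_species(
            Species(
                name=cname,
                role=_LIGATION_ROLES[cname],
                constituents=tuple(sorted((a, b))),
            )
        )
        net.add_reaction(
            Reaction(
                reactants=(a, b),
                product=cname,
                kon=registry[f"kon_{key}"],
                koff=registry[f"koff_{key}"],
            )
        )
    return net


def build_drug_binding(drug: DrugSpec, network: ReactionNetwork) -> ReactionNetwork:
    """Add a drug's binding reactions to a copy of ``network``.

    mAb: one dimer species, one reversible reaction.  BsAb: two dimers, one
    trimer, four reversible reactions, with the crosslink factor ``alpha``
    multiplying the trimer-forming on-rate on both association paths.
    A blocking-arm-bound checkpoint is sequestered: the complex carries the
    ``neutral`` role and feeds no regulatory link downstream.
    """
    net = network.copy()
    for arm in drug.arms:
        if arm.target not in net.species:
            raise MissingSpeciesError(
                f"{drug.name}: target {arm.target!r} absent from the compartment"
            )
    net.add_species(Species(name=drug.name, carrier=None))
    arm_role = {
        a.target: ("stimulatory" if a.mode == "agonist" else "neutral")
        for a in drug.arms
    }
    dimers = []
    for arm in drug.arms:
        dname = f"{drug.name}:{arm.target}"
        net.add_species(
            Species(
                name=dname,
                role=arm_role[arm.target],
                constituents=tuple(sorted((drug.name, arm.target))),
            )
        )
        net.add_reaction(
            Reaction(
                reactants=(drug.name, arm.target),
                product=dname,
                kon=arm.kon,
                koff=arm.koff,
            )
        )
        dimers.append(dname)
    if drug.modality == "BsAb":
        a1, a2 = drug.arms
        tname = f"{a1.target}:{drug.name}:{a2.target}"
        trimer_role = (
            "stimulatory"
            if any(a.mode == "agonist" for a in drug.arms)
            else "neutral"
        )
        net.add_species(
            Species(
                name=tname,
                role=trimer_role,
                constituents=tuple(sorted((drug.name, a1.target, a2.target))),
            )
        )
        # path via dimer with arm1 engaged picks up the free arm-2 target
        net.add_reaction(
            Reaction(
                reactants=(dimers[0], a2.target),
                product=tname,
                kon=drug.alpha * a2.kon,
                koff=a2.koff,
            )
        )
        net.add_reaction(
            Reaction(
                reactants=(dimers[1], a1.target),
                product=tname,
                kon=drug.alpha * a1.kon,
                koff=a1.koff,
            )
        )
    return net


# --------------------------------------------------------------------------
# algebraic equilibrium solver
# --------------------------------------------------------------------------

@dataclass
class _Cluster:
    """One connected component of the binding graph, solved independently."""

    s_idx: np.ndarray  # base species indices
    c_idx: np.ndarray  # complex indices
    nu: np.ndarray  # (n_complex, n_species) stoichiometry within the cluster
    logK: np.ndarray  # (n_complex,) log association constants
    is_pair: bool = False  # single A + B <-> C cluster: closed form


class EquilibriumProblem:
    """Steady state of a closed mass-action binding network from totals.

    Complexes are expressed through free concentrations and cumulative
    association constants, ``C = K_C * prod_s x_s^nu``, which encodes every
    equilibrium relation; the remaining unknowns are the free base species,
    fixed by conservation ``x_s + sum_C nu_Cs C = T_s``.  The system is
    solved per independent cluster with a damped Newton iteration in
    log-concentration space (batched over parameter sets), with a closed-form
    quadratic shortcut for isolated pairs.
    """

    def __init__(self, base: list[str], complexes: list[str],
                 nu: np.ndarray, logK: np.ndarray):
        self.base = list(base)
        self.complexes = list(complexes)
        self.nu = np.asarray(nu, dtype=float)
        self.logK = np.asarray(logK, dtype=float)
        self._warm: dict[int, np.ndarray] = {}
        self._clusters = self._decompose()
        # vectorized closed-form path across all isolated-pair clusters
        pairs = [cl for cl in self._clusters if cl.is_pair]
        self._newton_clusters = [
            cl for cl in self._clusters if not cl.is_pair and len(cl.c_idx)
        ]
        self._free_idx = np.concatenate(
            [cl.s_idx for cl in self._clusters if not len(cl.c_idx)]
        ).astype(int) if any(not len(cl.c_idx) for cl in self._clusters) else np.zeros(0, dtype=int)
        self._pair_r = np.array([cl.s_idx[0] for cl in pairs], dtype=int)
        self._pair_l = np.array([cl.s_idx[1] for cl in pairs], dtype=int)
        self._pair_c = np.array([cl.c_idx[0] for cl in pairs], dtype=int)
        self._pair_kd = np.array([math.exp(-cl.logK[0]) for cl in pairs])
        self._absent_mask = (self.nu.T > 0).astype(float)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_network(cls, net: ReactionNetwork) -> "EquilibriumProblem":
        base = net.base_species
        complexes = net.complex_species
        b_idx = {n: i for i, n in enumerate(base)}
        nu = np.zeros((len(complexes), len(base)))
        logK = np.full(len(complexes), np.nan)
        for ci, cname in enumerate(complexes):
            for constituent in net.composition_of(cname):
                nu[ci, b_idx[constituent]] += 1.0
        # resolve cumulative K by walking formation reactions until fixed point
        logk_sp: dict[str, float] = {n: 0.0 for n in base}
        pending = list(net.reactions)
        guard = 0
        while pending and guard < 10 * len(net.reactions):
            guard += 1
            rxn = pending.pop(0)
            a, b = rxn.reactants
            if a in logk_sp and b in logk_sp:
                val = logk_sp[a] + logk_sp[b] + math.log(rxn.kon / rxn.koff)
                if rxn.product in logk_sp:
                    if abs(val - logk_sp[rxn.product]) > 1e-8:
                        raise ValueError(
                            f"thermodynamic cycle inconsistency at {rxn.product}: "
                            f"logK {val} vs {logk_sp[rxn.product]}"
                        )
                else:
                    logk_sp[rxn.product] = val
            else:
                pending.append(rxn)
        for ci, cname in enumerate(complexes):
            logK[ci] = logk_sp[cname]
        return cls(base, complexes, nu, logK)

    def _decompose(self) -> list[_Cluster]:
        n_s = len(self.base)
        parent = list(range(n_s))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

        for ci in range(len(self.complexes)):
            members = np.nonzero(self.nu[ci] > 0)[0]
            for m in members[1:]:
                union(members[0], m)
        groups: dict[int, list[int]] = {}
        for s in range(n_s):
            groups.setdefault(find(s), []).append(s)
        clusters = []
        for members in groups.values():
            s_idx = np.array(sorted(members))
            in_cluster = np.zeros(n_s, dtype=bool)
            in_cluster[s_idx] = True
            c_idx = np.array(
                [
                    ci
                    for ci in range(len(self.complexes))
                    if in_cluster[np.nonzero(self.nu[ci] > 0)[0]].all()
                    and (self.nu[ci] > 0).any()
                ],
                dtype=int,
            )
            nu_local = self.nu[np.ix_(c_idx, s_idx)] if len(c_idx) else np.zeros((0, len(s_idx)))
            is_pair = (
                len(c_idx) == 1
                and len(s_idx) == 2
                and np.array_equal(np.sort(nu_local.ravel()), [1.0, 1.0])
            )
            clusters.append(
                _Cluster(
                    s_idx=s_idx,
                    c_idx=c_idx,
                    nu=nu_local,
                    logK=self.logK[c_idx] if len(c_idx) else np.zeros(0),
                    is_pair=is_pair,
                )
            )
        return clusters

    # -- solving -----------------------------------------------------------
    def solve(
        self,
        totals: Mapping[str, float] | np.ndarray,
        warm_start: bool = False,
        tol: float = 1e-12,
        max_iter: int = 200,
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Free base-species and complex concentrations from totals.

        ``totals`` is a name->nM mapping or an array ``(n_base,)`` /
        ``(batch, n_base)``.  Returns ``(free, complexes, residual)`` where
        the residual is the worst relative conservation error.
        """
        if isinstance(totals, Mapping):
            arr = np.array([float(totals.get(n, 0.0)) for n in self.base])
        else:
            arr = np.asarray(totals, dtype=float)
        squeeze = arr.ndim == 1
        T = arr[None, :] if squeeze else arr
        if T.shape[1] != len(self.base):
            raise ValueError("totals shape does not match base species")
        if np.any(T < 0):
            raise ValueError("totals must be non-negative")
        B = T.shape[0]
        x = np.zeros_like(T)
        c = np.zeros((B, len(self.complexes)))
        worst = 0.0
        if self._free_idx.size:
            x[:, self._free_idx] = T[:, self._free_idx]
        if self._pair_r.size:
            r = T[:, self._pair_r]
            l = T[:, self._pair_l]
            b = equilibrium_bimolecular(r, l, self._pair_kd[None, :])
            b = np.minimum(b, np.minimum(r, l))
            x[:, self._pair_r] = r - b
            x[:, self._pair_l] = l - b
            c[:, self._pair_c] = b
        for k, cl in enumerate(self._newton_clusters):
            Tc = np.maximum(T[:, cl.s_idx], _TOTAL_FLOOR)
            x0 = None
            if warm_start:
                prev = self._warm.get(k)
                if prev is not None and prev.shape == Tc.shape:
                    x0 = np.minimum(prev, Tc)
            xc, cc, res = _newton_cluster(cl.nu, cl.logK, Tc, x0, tol, max_iter)
            worst = max(worst, res)
            if warm_start:
                self._warm[k] = xc
            x[:, cl.s_idx] = np.where(T[:, cl.s_idx] > 0, xc, 0.0)
            c[:, cl.c_idx] = cc
        # zero out complexes containing a truly absent species
        absent = T <= 0
        if absent.any():
            has_absent = (absent @ self._absent_mask) > 0
            c = np.where(has_absent, 0.0, c)
        if squeeze:
            return x[0], c[0], worst
        return x, c, worst

    def solve_dict(self, totals: Mapping[str, float], **kw) -> tuple[dict, float]:
        x, c, res = self.solve(totals, **kw)
        out = {n: float(v) for n, v in zip(self.base, x)}
        out.update({n: float(v) for n, v in zip(self.complexes, c)})
        return out, res


def _newton_cluster(nu, logK, T, x0, tol, max_iter):
    """Damped Newton in log-free-concentration space for one cluster batch."""
    Bn, S = T.shape
    x = 0.5 * T if x0 is None else np.maximum(x0, _TOTAL_FLOOR)
    u = np.log(x)
    lo = np.log(_TOTAL_FLOOR) - 10.0
    res = np.inf
    for _ in range(max_iter):
        x = np.exp(u)
        logc = logK[None, :] + u @ nu.T
        cc = np.exp(np.clip(logc, -700.0, 700.0))
        G = (x + cc @ nu) / T - 1.0
        res = np.max(np.abs(G))
        if res < tol:
            break
        # J[b,s,t] = (delta_st x_s + sum_c nu_cs nu_ct c_c) / T_s
        J = np.einsum("bc,cs,ct->bst", cc, nu, nu)
        J[:, np.arange(S), np.arange(S)] += x
        J /= T[:, :, None]
        try:
            du = np.linalg.solve(J, G[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - singular fallback
            du = G
        du = np.clip(du, -4.0, 4.0)
        if res > 1e-2:
            # far from the solution: backtrack on the residual norm
            base_norm = (G * G).sum(axis=1)
            step = np.ones((Bn, 1))
            for _bt in range(8):
                u_new = np.clip(u - step * du, lo, 700.0)
                x_new = np.exp(u_new)
                c_new = np.exp(np.clip(logK[None, :] + u_new @ nu.T, -700.0, 700.0))
                G_new = (x_new + c_new @ nu) / T - 1.0
                bad = (G_new * G_new).sum(axis=1) > base_norm * (1.0 - 1e-4)
                if not bad.any():
                    break
                step[bad] *= 0.5
            u = np.clip(u - step * du, lo, 700.0)
        else:
            # local quadratic convergence regime: plain Newton step
            u = np.clip(u - du, lo, 700.0)
    x = np.exp(u)
    cc = np.exp(np.clip(logK[None, :] + u @ nu.T, -700.0, 700.0))
    G = (x + cc @ nu) / T - 1.0
    res = float(np.max(np.abs(G)))
    if res > 1e-6:
        raise RuntimeError(
            f"equilibrium solve did not converge: residual norm {res:.3e}"
        )
    return x, cc, res


def steady_state_network(
    network: ReactionNetwork,
    totals: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Equilibrium concentrations of every species in a closed network.

    Satisfies all equilibrium relations and conservation laws; agreement
    with long-time kinetic integration is enforced in the test suite.
    """
    problem = network.equilibrium_problem()
    conc, _res = problem.solve_dict(totals if totals is not None else network.totals())
    return conc


def ctla4_competition_relief(
    network: ReactionNetwork,
    anti_ctla4_grid: Sequence[float],
    totals: Mapping[str, float],
    drug_name: str = "anti-CTLA4",
) -> np.ndarray:
    """CD28-CD80/86 occupancy across an anti-CTLA4 concentration grid.

    A blocking anti-CTLA4 sequesters CTLA4 and frees the shared CD80/86
    pool for CD28, so the costimulatory occupancy is non-decreasing in
    drug concentration.
    """
    if drug_name not in network.species:
        raise MissingSpeciesError(drug_name)
    problem = network.equilibrium_problem()
    out = np.empty(len(anti_ctla4_grid))
    for i, conc in enumerate(anti_ctla4_grid):
        tot = dict(totals)
        tot[drug_name] = float(conc)
        conc_map, _ = problem.solve_dict(tot)
        out[i] = conc_map["CD28:CD8086"]
    return out
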