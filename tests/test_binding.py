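import math

import numpy as np
import pytest

from immunoqsp.binding import (
    EquilibriumProblem,
    MissingSpeciesError,
    Reaction,
    ReactionNetwork,
    Species,
    build_checkpoint_binding,
    build_drug_binding,
    ctla4_competition_relief,
    equilibrium_bimolecular,
    steady_state_network,
)
from immunoqsp.model_config import make_bsab, make_mab


def make_pair(kon=10.0, koff=5.0):
    net = ReactionNetwork()
    net.add_species(Species("R"))
    net.add_species(Species("L"))
    net.add_reaction(Reaction(("R", "L"), "R:L", kon, koff))
    return net


def random_small_network(rng):
    """Random binding network with <= 6 base species, possibly with a
    bispecific-style dimer/trimer motif and a shared-ligand competition."""
    net = ReactionNetwork()
    n_base = rng.integers(2, 5)
    names = [f"S{i}" for i in range(n_base)]
    for n in names:
        net.add_species(Species(n))
    # pairwise ligations over a random subset
    for i in range(n_base - 1):
        if rng.random() < 0.7:
            kon = 10 ** rng.uniform(0, 2)
            koff = 10 ** rng.uniform(-1, 2)
            net.add_reaction(Reaction((names[i], names[i + 1]), f"{names[i]}:{names[i+1]}", kon, koff))
    if rng.random() < 0.5 and n_base >= 3:
        # drug D bridging S0 and S1 (dimer -> trimer with crosslink)
        net.add_species(Species("D"))
        k1, k2 = 10 ** rng.uniform(0, 1.5), 10 ** rng.uniform(0, 1.5)
        o1, o2 = 10 ** rng.uniform(0, 1.5), 10 ** rng.uniform(0, 1.5)
        alpha = 10 ** rng.uniform(0, 1.5)
        net.add_reaction(Reaction(("D", names[0]), "D:S0", k1, o1))
        net.add_reaction(Reaction(("D", names[1]), "D:S1", k2, o2))
        net.add_reaction(Reaction(("D:S0", names[1]), "S0:D:S1", alpha * k2, o2))
        net.add_reaction(Reaction(("D:S1", names[0]), "S0:D:S1", alpha * k1, o1))
    totals = {n: 10 ** rng.uniform(-2, 1) for n in net.base_species}
    return net, totals


class TestBimolecularOracle:
    @pytest.mark.parametrize(
        "r,l,kd,expected",
        [
            (0.0, 10.0, 5.0, 0.0),
            (5.0, 10.0, 0.0, 5.0),  # tight-binding limit
            (10.0, 10.0, 10.0, 3.8196601125010515),
        ],
    )
    def test_known_values(self, r, l, kd, expected):
        assert equilibrium_bimolecular(r, l, kd) == pytest.approx(expected, rel=1e-12)

    def test_matches_polynomial_root(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r, l, kd = 10 ** rng.uniform(-3, 3, size=3)
            b = equilibrium_bimolecular(r, l, kd)
            roots = np.roots([1.0, -(r + l + kd), r * l])
            physical = [x for x in roots if -1e-12 <= x <= min(r, l) * (1 + 1e-9)]
            assert b == pytest.approx(min(physical, key=lambda x: abs(x - b)), rel=1e-9)
            assert 0 <= b <= min(r, l) + 1e-12

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_bimolecular(-1.0, 1.0, 1.0)


class TestSteadyState:
    def test_single_pair_matches_quadratic(self):
        net = make_pair(kon=10.0, koff=5.0)
        conc = steady_state_network(net, {"R": 3.0, "L": 7.0})
        expected = equilibrium_bimolecular(3.0, 7.0, 0.5)
        assert conc["R:L"] == pytest.approx(expected, rel=1e-6)

    def test_totals_preserved(self):
        net = make_pair()
        conc = steady_state_network(net, {"R": 2.0, "L": 9.0})
        assert conc["R"] + conc["R:L"] == pytest.approx(2.0, rel=1e-9)
        assert conc["L"] + conc["R:L"] == pytest.approx(9.0, rel=1e-9)

    def test_affinity_ordering_in_competition(self, registry, profiles):
        """10x tighter CTLA4 binding wins the shared CD80/86 pool at equal totals."""
        net = ReactionNetwork()
        for n in ("CTLA4", "CD28", "L"):
            net.add_species(Species(n))
        net.add_reaction(Reaction(("CTLA4", "L"), "CTLA4:L", 100.0, 1.0))
        net.add_reaction(Reaction(("CD28", "L"), "CD28:L", 100.0, 10.0))
        conc = steady_state_network(net, {"CTLA4": 1.0, "CD28": 1.0, "L": 1.0})
        assert conc["CTLA4:L"] > conc["CD28:L"]

    def test_agrees_with_kinetic_integration(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            net, totals = random_small_network(rng)
            if not net.reactions:
                continue
            _, traj = net.simulate_kinetics(2000.0, totals, n_out=5)
            algebraic = steady_state_network(net, totals)
            for name in net.species:
                kin = traj[name][-1]
                alg = algebraic[name]
                scale = max(totals.get(name, 0.0), 1e-9, kin)
                assert abs(kin - alg) / scale < 1e-5

    def test_zero_total_species(self):
        net = make_pair()
        conc = steady_state_network(net, {"R": 1.0, "L": 0.0})
        assert conc["R:L"] == 0.0
        assert conc["R"] == pytest.approx(1.0)


class TestNetworkBuilders:
    def test_cd8086_shared_between_cd28_and_ctla4(self, checkpoint_network):
        uses = [r for r in checkpoint_network.reactions if "CD8086" in r.reactants]
        assert len(uses) == 2
        partners = {r.reactants[0] for r in uses}
        assert partners == {"CD28", "CTLA4"}

    def test_missing_partner_raises(self, registry, profiles):
        from immunoqsp.model_config import CheckpointProfiles

        crippled = CheckpointProfiles(
            expression={
                "T": dict(profiles.expression["T"]),
                "tumor": {k: v for k, v in profiles.expression["tumor"].items() if k != "CD155"},
                "APC": {k: v for k, v in profiles.expression["APC"].items() if k != "CD155"},
            }
        )
        with pytest.raises(MissingSpeciesError):
            build_checkpoint_binding(crippled, registry)

    def test_mab_adds_one_dimer_one_reaction(self, checkpoint_network, registry):
        drug = make_mab("PD-1", registry)
        net = build_drug_binding(drug, checkpoint_network)
        assert len(net.species) == len(checkpoint_network.species) + 2  # drug + dimer
        assert len(net.reactions) == len(checkpoint_network.reactions) + 1

    def test_bsab_adds_dimers_trimer_four_reactions(self, checkpoint_network, registry):
        drug = make_bsab("TIGIT", "PD-L1", registry)
        net = build_drug_binding(drug, checkpoint_network)
        new_species = set(net.species) - set(checkpoint_network.species)
        assert new_species == {
            drug.name,
            f"{drug.name}:TIGIT",
            f"{drug.name}:PD-L1",
            f"TIGIT:{drug.name}:PD-L1",
        }
        assert len(net.reactions) == len(checkpoint_network.reactions) + 4

    def test_trimer_cycle_consistency(self, checkpoint_network, registry):
        """Both dimer->trimer paths give the same cumulative association
        constant, so the thermodynamic cycle closes by construction."""
        drug = make_bsab("TIGIT", "PD-L1", registry)
        net = build_drug_binding(drug, checkpoint_network)
        # resolving the problem raises if the cycle were inconsistent
        problem = EquilibriumProblem.from_network(net)
        tname = f"TIGIT:{drug.name}:PD-L1"
        k_paths = []
        for first, second in (("TIGIT", "PD-L1"), ("PD-L1", "TIGIT")):
            k = 1.0
            for rxn in net.reactions:
                if rxn.product == f"{drug.name}:{first}":
                    k *= rxn.keq
                if rxn.product == tname and f"{drug.name}:{first}" in rxn.reactants:
                    k *= rxn.keq
            k_paths.append(k)
        assert k_paths[0] == pytest.approx(k_paths[1], rel=1e-9)

    def test_inconsistent_cycle_rejected(self):
        net = ReactionNetwork()
        for n in ("A", "B", "D"):
            net.add_species(Species(n))
        net.add_reaction(Reaction(("D", "A"), "D:A", 10.0, 1.0))
        net.add_reaction(Reaction(("D", "B"), "D:B", 10.0, 1.0))
        net.add_reaction(Reaction(("D:A", "B"), "A:D:B", 10.0, 1.0))
        # second path with a different alpha on only one leg breaks the cycle
        net.add_reaction(Reaction(("D:B", "A"), "A:D:B", 99.0, 1.0))
        with pytest.raises(ValueError, match="cycle"):
            EquilibriumProblem.from_network(net)

    def test_drug_target_absent_raises(self, checkpoint_network, registry):
        drug = make_mab("PD-1", registry)
        drug.arms[0].target = "GITR"
        with pytest.raises(MissingSpeciesError):
            build_drug_binding(drug, checkpoint_network)


class TestConservationAndMonotonicity:
    def test_kinetic_trajectory_conserves_totals(self, checkpoint_network, registry, invivo_totals):
        drug = make_bsab("TIGIT", "PD-L1", registry)
        net = build_drug_binding(drug, checkpoint_network)
        totals = dict(invivo_totals)
        totals[drug.name] = 10.0
        t, traj = net.simulate_kinetics(5.0, totals, n_out=20)
        conserved = net.conserved_totals(traj)
        for base, series in conserved.items():
            tot = totals.get(base, 0.0)
            if tot > 0:
                assert np.max(np.abs(series - tot)) / tot < 1e-6

    def test_blocking_drug_depletes_target_complex_monotonically(
        self, checkpoint_network, registry, invivo_totals
    ):
        drug = make_mab("PD-1", registry)
        net = build_drug_binding(drug, checkpoint_network)
        problem = net.equilibrium_problem()
        levels = []
        for conc in [0.0, 1.0, 3.0, 10.0, 30.0, 100.0]:
            totals = dict(invivo_totals)
            totals[drug.name] = conc
            sol, _ = problem.solve_dict(totals)
            levels.append(sol["PD-1:PD-L1"])
        assert all(b < a for a, b in zip(levels, levels[1:]))

    def test_zero_cd155_gives_zero_tigit_flux(self, checkpoint_network, invivo_totals):
        totals = dict(invivo_totals)
        totals["CD155"] = 0.0
        conc = steady_state_network(checkpoint_network, totals)
        assert conc["TIGIT:CD155"] == 0.0


class TestCtla4Relief:
    def test_monotone_relief_and_limits(self, checkpoint_network, registry, invivo_totals):
        drug = make_mab("CTLA4", registry)
        net = build_drug_binding(drug, checkpoint_network)
        grid = np.concatenate([[0.0], np.logspace(-2, 4, 10)])
        occ = ctla4_competition_relief(net, grid, invivo_totals, drug_name=drug.name)
        assert np.all(np.diff(occ) >= -1e-12)  # non-decreasing in drug
        # infinite-drug limit approaches the CTLA4-free equilibrium
        free_totals = dict(invivo_totals)
        free_totals["CTLA4"] = 0.0
        no_ctla4 = steady_state_network(checkpoint_network, free_totals)["CD28:CD8086"]
        assert occ[-1] == pytest.approx(no_ctla4, rel=1e-3)
        # zero drug reproduces the baseline competition equilibrium
        baseline = steady_state_network(checkpoint_network, invivo_totals)["CD28:CD8086"]
        assert occ[0] == pytest.approx(baseline, rel=1e-9)
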