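import copy

import numpy as np
import pandas as pd
import pytest

from immunoqsp import cells
from immunoqsp.engine import (
    SimulationResult,
    assemble_system,
    compute_tgi,
    simulate,
    simulate_invitro_cytotoxicity,
    simulate_invitro_stimulation,
    simulate_invivo,
)
from immunoqsp.model_config import (
    DoseRegimen,
    Treatment,
    default_scenario,
    make_bsab,
    make_mab,
)


def fabricate_result(t, volumes, config):
    states = {"tumor": np.atleast_2d(np.asarray(volumes, dtype=float))}
    return SimulationResult(t=np.asarray(t, dtype=float), states=states,
                            config=config, provenance={})


class TestAssembly:
    def test_layout_deterministic(self, invivo_config):
        a = assemble_system(invivo_config)
        b = assemble_system(copy.deepcopy(invivo_config))
        assert a.problem.base == b.problem.base
        assert a.problem.complexes == b.problem.complexes

    def test_no_drug_means_no_drug_species(self, invivo_config):
        sys_ = assemble_system(invivo_config.control())
        assert not any("anti-" in s for s in sys_.problem.base)

    def test_bsab_adds_three_complexes(self, invivo_config):
        drug = make_bsab("TIGIT", "PD-L1", invivo_config.registry)
        cfg = invivo_config.with_treatments(
            [Treatment(drug=drug, regimen=DoseRegimen.qw(1.0, 25.0))]
        )
        base = assemble_system(invivo_config.control())
        sys_ = assemble_system(cfg)
        new = set(sys_.problem.complexes) - set(base.problem.complexes)
        assert len(new) == 3  # two dimers + one trimer


class TestReductions:
    def test_kill_disabled_run_is_exactly_logistic(self, invivo_config):
        cfg = invivo_config.control()
        cfg = copy.deepcopy(cfg)
        cfg.registry.set_value("kkill_tumor", 0.0)
        res = simulate_invivo(cfg)
        kg = cfg.registry["kg_tumor"]
        vmax = cfg.registry["Vmax_tumor"]
        closed = cells.logistic_solution(res.t, cfg.v0_mm3, kg, vmax)
        assert np.max(np.abs(res.states["tumor"][0] - closed) / closed) < 1e-6

    def test_zero_dose_equals_drug_absent(self, invivo_config, control_run):
        drug = make_mab("PD-1", invivo_config.registry)
        cfg = invivo_config.with_treatments(
            [Treatment(drug=drug, regimen=DoseRegimen(0.0, (0.0, 7.0)))]
        )
        res = simulate_invivo(cfg)
        ref = control_run.states["tumor"][0]
        assert np.max(np.abs(res.states["tumor"][0] - ref) / ref) < 1e-6

    def test_bit_reproducible(self, invivo_config):
        cfg = invivo_config.control()
        a = simulate(cfg)
        b = simulate(cfg)
        assert np.array_equal(a.states["tumor"], b.states["tumor"])
        assert a.provenance["config_hash"] == b.provenance["config_hash"]


class TestStimulation:
    def test_no_stimulus_is_flat(self):
        cfg = default_scenario("invitro_stimulation", horizon=0.3, n_out=50)
        res = simulate_invitro_stimulation(cfg)
        for hub in ("ZAP70", "PI3K", "AKT", "ERK", "NFkB"):
            assert res.states[hub].max() == pytest.approx(0.0, abs=1e-12)

    def test_anti_cd3_transient_and_costimulation(self):
        cfg = default_scenario("invitro_stimulation", horizon=0.5, n_out=200)
        acd3 = make_mab("TCR", cfg.registry, mode="agonist", name="anti-CD3")
        acd28 = make_mab("CD28", cfg.registry, mode="agonist", name="anti-CD28")
        single = simulate_invitro_stimulation(
            cfg.with_treatments([Treatment(drug=acd3, bath_nM=20.0)])
        )
        z = single.states["ZAP70"][0]
        assert z.max() >= 1.2 * z[-1]  # rise-then-fall transient
        both = simulate_invitro_stimulation(
            cfg.with_treatments(
                [Treatment(drug=acd3, bath_nM=20.0), Treatment(drug=acd28, bath_nM=20.0)]
            )
        )
        assert both.states["AKT"][0].max() > single.states["AKT"][0].max()
        # upstream precedes downstream: time to half-max ordering
        def t_half(res, name):
            x = res.states[name][0]
            return res.t[np.argmax(x >= 0.5 * x.max())]

        assert t_half(single, "ZAP70") <= t_half(single, "ERK")
        assert t_half(single, "ZAP70") <= t_half(single, "NFkB")

    def test_normalized_traces_peak_at_one(self):
        cfg = default_scenario("invitro_stimulation", horizon=0.3, n_out=100)
        acd3 = make_mab("TCR", cfg.registry, mode="agonist", name="anti-CD3")
        res = simulate_invitro_stimulation(
            cfg.with_treatments([Treatment(drug=acd3, bath_nM=20.0)])
        )
        assert res.states["norm_ZAP70"].max() == pytest.approx(1.0)


class TestCytotoxicity:
    def test_blocking_mab_dose_response_monotone(self):
        cfg = default_scenario("invitro_coculture")
        drug = make_mab("PD-1", cfg.registry)
        table = simulate_invitro_cytotoxicity(cfg, drug, [1.0, 10.0, 100.0, 1000.0])
        assert np.all(np.diff(table["pct_killing"]) >= -1e-9)
        assert np.all(np.diff(table["ifng_fold"]) >= -1e-9)

    def test_saturating_blockade_approaches_knockout(self):
        cfg = default_scenario("invitro_coculture")
        drug = make_mab("PD-1", cfg.registry)
        sat = simulate(cfg.with_treatments([Treatment(drug=drug, bath_nM=2000.0)]))
        ko_cfg = default_scenario("invitro_coculture")
        ko_cfg.registry.set_value(
            "PD-1_per_cell", ko_cfg.registry.entry("PD-1_per_cell").lower
        )
        ko = simulate(ko_cfg.control())
        n_sat, n_ko = sat.states["tumor"][0, -1], ko.states["tumor"][0, -1]
        assert abs(n_sat - n_ko) / n_ko < 0.01


class TestTGI:
    def test_equal_arms_give_zero(self, invivo_config):
        t = np.linspace(0, 25, 5)
        a = fabricate_result(t, [100, 300, 700, 1200, 2000], invivo_config)
        b = fabricate_result(t, [100, 300, 700, 1200, 2000], invivo_config)
        assert compute_tgi(a, b)[0] == pytest.approx(0.0)

    def test_definition_arithmetic(self, invivo_config):
        t = np.array([0.0, 25.0])
        treated = fabricate_result(t, [100, 500], invivo_config)
        control = fabricate_result(t, [100, 2000], invivo_config)
        assert compute_tgi(treated, control)[0] == pytest.approx(75.0)

    def test_eradication_approaches_100(self, invivo_config):
        t = np.array([0.0, 25.0])
        treated = fabricate_result(t, [100, 1e-9], invivo_config)
        control = fabricate_result(t, [100, 2000], invivo_config)
        assert compute_tgi(treated, control)[0] == pytest.approx(100.0)

    def test_mismatched_grids_rejected(self, invivo_config):
        a = fabricate_result([0, 10], [100, 200], invivo_config)
        b = fabricate_result([0, 12], [100, 200], invivo_config)
        with pytest.raises(ValueError):
            compute_tgi(a, b)

    def test_delta_convention(self, invivo_config):
        cfg = copy.deepcopy(invivo_config)
        cfg.options["tgi_convention"] = "delta"
        t = np.array([0.0, 25.0])
        treated = fabricate_result(t, [100, 600], cfg)
        control = fabricate_result(t, [100, 1100], cfg)
        assert compute_tgi(treated, control)[0] == pytest.approx(50.0)


class TestNumerics:
    def test_tolerance_robustness(self, invivo_config, control_run):
        tight = copy.deepcopy(invivo_config.control())
        tight.solver.rtol = invivo_config.solver.rtol / 10
        tight.solver.atol = invivo_config.solver.atol / 10
        res = simulate(tight)
        v_ref = control_run.at_day("tumor", 25.0)[0]
        v_tight = res.at_day("tumor", 25.0)[0]
        assert abs(v_tight - v_ref) / v_ref < 1e-3

    def test_states_stay_physical(self, invivo_config):
        drug = make_bsab("4-1BB", "PD-L1", invivo_config.registry)
        cfg = invivo_config.with_treatments(
            [Treatment(drug=drug, regimen=DoseRegimen.qw(10.0, 25.0))]
        )
        res = simulate(cfg)
        for hub in ("ZAP70", "PI3K", "AKT", "ERK", "NFkB"):
            assert res.states[hub].min() >= -1e-9
            assert res.states[hub].max() <= 1 + 1e-9
        assert res.states["tumor"].min() >= 0
        assert res.states["N_T"].min() >= 0

    def test_weaker_bsab_binding_is_less_effective(self, invivo_config, control_run):
        strong = make_bsab("TIGIT", "PD-L1", invivo_config.registry)
        weak = make_bsab("TIGIT", "PD-L1", invivo_config.registry)
        for arm in weak.arms:
            arm.koff *= 2.0  # both arms bind 2x weaker
        def final_v(drug):
            cfg = invivo_config.with_treatments(
                [Treatment(drug=drug, regimen=DoseRegimen.qw(1.0, 25.0))]
            )
            return simulate(cfg).states["tumor"][0, -1]

        assert final_v(weak) >= final_v(strong)


class TestBatching:
    def test_override_batch_matches_separate_runs(self, invivo_config):
        cfg = invivo_config.control()
        ov = pd.DataFrame({"kg_tumor": [0.3, 0.5]})
        batched = simulate(cfg, ov)
        for i, kg in enumerate([0.3, 0.5]):
            single_cfg = copy.deepcopy(cfg)
            single_cfg.registry.set_value("kg_tumor", kg)
            single = simulate(single_cfg)
            ref = single.states["tumor"][0]
            assert np.max(np.abs(batched.states["tumor"][i] - ref) / ref) < 1e-4

    def test_unknown_override_rejected(self, invivo_config):
        with pytest.raises(KeyError):
            simulate(invivo_config.control(), pd.DataFrame({"not_a_param": [1.0]}))
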