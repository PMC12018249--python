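import itertools

import numpy as np
import pandas as pd
import pytest

from immunoqsp.population import (
    PopulationSpec,
    apply_subgroup,
    default_population_spec,
    response_depth_bins,
    sample_population,
    sobol_total_order,
    wilcoxon_ranksum,
    _holm,
)


class TestSampling:
    def test_default_population_has_100_mice(self):
        pop = sample_population(seed=0)
        assert pop.n == 100

    def test_same_seed_identical(self):
        a = sample_population(seed=5)
        b = sample_population(seed=5)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_different_seed_differs(self):
        a = sample_population(seed=5)
        b = sample_population(seed=6)
        assert not a.params.equals(b.params)

    def test_marginals_within_ranges(self):
        pop = sample_population(seed=2)
        for name, (lo, hi, _) in pop.spec.ranges.items():
            col = pop.params[name]
            assert col.min() >= lo and col.max() <= hi

    def test_latin_hypercube_stratification(self):
        """Each of n equal-probability bins is hit exactly once per dimension."""
        pop = sample_population(seed=3)
        n = pop.n
        for name, (lo, hi, scale) in pop.spec.ranges.items():
            x = pop.params[name].to_numpy()
            u = (np.log(x / lo) / np.log(hi / lo)) if scale == "log" else (x - lo) / (hi - lo)
            bins = np.floor(u * n).astype(int)
            assert sorted(bins) == list(range(n))

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(ranges={"x": (2.0, 1.0, "linear")})

    def test_equal_bounds_allowed(self):
        spec = PopulationSpec(ranges={"kg_tumor": (0.3, 0.3, "linear")}, n=10)
        pop = sample_population(spec, seed=0)
        assert np.all(pop.params["kg_tumor"] == 0.3)


class TestSubgroups:
    def test_low_subgroup_confined_to_lower_decile(self):
        pop = sample_population(seed=4)
        low = apply_subgroup(pop, "PD-1")
        lo, hi, scale = pop.spec.ranges["PD-1_per_cell"]
        decile_hi = lo * (hi / lo) ** 0.1  # log-scale decile boundary
        assert low.params["PD-1_per_cell"].max() <= decile_hi
        # other columns untouched
        other = [c for c in pop.params.columns if c != "PD-1_per_cell"]
        pd.testing.assert_frame_equal(pop.params[other], low.params[other])

    def test_subgroup_reproducible(self):
        a = apply_subgroup(sample_population(seed=4), "TIGIT")
        b = apply_subgroup(sample_population(seed=4), "TIGIT")
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_unknown_checkpoint_rejected(self):
        with pytest.raises(KeyError):
            apply_subgroup(sample_population(seed=0), "GITR")


def exact_ranksum_p(a, b):
    """Enumeration oracle: two-sided p over all rank assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[list(combo)])
        total += 1
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        w, p = wilcoxon_ranksum([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    def test_separated_small_samples_exact(self):
        w, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_ranksum_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])))

    def test_symmetry(self):
        a, b = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
        assert wilcoxon_ranksum(a, b)[1] == pytest.approx(wilcoxon_ranksum(b, a)[1])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 6)
            _, p = wilcoxon_ranksum(a, b)
            assert p == pytest.approx(exact_ranksum_p(a, b), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestBinsAndHolm:
    def test_bins_partition_any_population(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            tgi = rng.uniform(-20, 110, 100)
            bins = response_depth_bins(tgi)
            assert sum(bins.values()) == pytest.approx(100.0)

    def test_bin_edges(self):
        bins = response_depth_bins(np.array([40.0, 39.9, 20.0, 20.1, 90.0]))
        assert bins["deep (>=40%)"] == pytest.approx(40.0)
        assert bins["partial (20-40%)"] == pytest.approx(40.0)
        assert bins["low (<=20%)"] == pytest.approx(20.0)

    def test_holm_is_monotone_and_bounded(self):
        raw = [0.04, 0.01, 0.3]
        adj = _holm(raw)
        assert adj == pytest.approx([0.08, 0.03, 0.3])
        assert all(a <= 1 for a in adj)


class TestSobol:
    def test_additive_model_total_equals_first_order(self):
        def linear(df):
            return 2.0 * df["a"].to_numpy() + 0.5 * df["b"].to_numpy()

        res = sobol_total_order(
            {"a": (0, 1, "linear"), "b": (0, 1, "linear")},
            linear, n=256, seed=0, n_boot=20,
        )
        assert np.allclose(res.total_order, res.first_order, atol=0.05)

    def test_inert_parameter_has_zero_total_order(self):
        def f(df):
            return np.sin(df["a"].to_numpy() * 3)

        res = sobol_total_order(
            {"a": (0, 1, "linear"), "dead": (1.0, 1.0, "linear")},
            f, n=256, seed=0, n_boot=20,
        )
        dead = res.total_order[res.names.index("dead")]
        assert abs(dead) < 0.05

    def test_requires_power_of_two(self):
        with pytest.raises(ValueError):
            sobol_total_order({"a": (0, 1, "linear")}, lambda df: df["a"].to_numpy(), n=100)

    def test_failed_evaluations_are_imputed_and_counted(self):
        def flaky(df):
            x = df["a"].to_numpy().copy()
            x[x > 0.95] = np.nan
            return x

        res = sobol_total_order({"a": (0, 1, "linear"), "b": (0, 1, "linear")},
                                flaky, n=64, seed=0, n_boot=10)
        assert res.n_failed > 0
        assert np.all(np.isfinite(res.total_order))
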