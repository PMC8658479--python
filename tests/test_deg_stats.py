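import math
from itertools import combinations
from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itx.deg_stats import (
    ContrastSpec,
    NullDistribution,
    build_null,
    call_degs,
    compute_lmr,
    compute_t,
    empirical_p,
    lmr_cutoff,
    stouffer_combine,
)
from itx.normalization import NormalizedMatrix
from itx.synthetic_data import DesignSpec, simulate_experiment

from conftest import normalize_full


class TestComputeT:
    def test_identical_groups(self):
        assert compute_t([1, 2, 3], [1, 2, 3]) == 0.0

    def test_textbook_pooled_formula(self):
        # means 2 and 5, pooled sd 1, se = sqrt(2/3)
        t = compute_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), abs=1e-12)
        assert t == pytest.approx(-3.674, abs=5e-4)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0], [0.5, 4.0, 4.5]
        assert compute_t(a, b) == -compute_t(b, a)

    def test_degenerate_variance(self):
        assert compute_t([2, 2], [2, 2]) == 0.0
        assert compute_t([3, 3], [2, 2]) == math.inf

    def test_short_group_rejected(self):
        with pytest.raises(ValueError):
            compute_t([1], [1, 2])


class TestComputeLmr:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 2, 3], [0, 1, 2], 1.0),
            ([0, 10], [4, 4], 1.0),  # even-length median = midpoint
        ],
    )
    def test_median_difference(self, a, b, expected):
        assert compute_lmr(a, b) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_lmr([], [1, 2])


class TestEmpiricalP:
    def null(self, values):
        return NullDistribution("t", np.asarray(values, float), 1, "exhaustive", 0)

    def test_zero_observation_has_p_one(self):
        assert empirical_p(0.0, self.null([-3, -1, 0, 1, 3])) == 1.0

    def test_boundary_minimum(self):
        null = self.null(np.linspace(-1, 1, 999))
        assert empirical_p(50.0, null) == pytest.approx(1.0 / 1000.0)

    def test_direct_count(self):
        assert empirical_p(2.0, self.null([-3, -1, 0, 1, 3])) == 0.5

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(float("nan"), self.null([1.0, 2.0]))


class TestEmpiricalPProperties:
    @given(
        null=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=1, max_size=200
        ),
        obs=st.floats(-100, 100, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_bounds_and_antitonicity_in_magnitude(self, null, obs):
        """p lies in [1/(N+1), 1] and never increases as |observed| grows."""
        dist = NullDistribution("t", np.asarray(null, float), 1, "exhaustive", 0)
        n = len(null)
        p = empirical_p(obs, dist)
        assert 1.0 / (n + 1) <= p <= 1.0
        assert empirical_p(2.0 * obs, dist) <= p


class TestStouffer:
    def test_uninformative_components(self):
        p, z = stouffer_combine(1.0, +1, 1.0, +1)
        assert p == 1.0 and z == 0.0

    def test_concordant_reinforcement(self):
        # closed form: z_i = Phi^-1(0.975) = 1.95996, Z = z_i * sqrt(2)
        p, z = stouffer_combine(0.05, +1, 0.05, +1)
        assert z == pytest.approx(2.77180, abs=1e-5)
        assert p == pytest.approx(2 * (1 - NormalDist().cdf(z)), abs=1e-12)
        assert p == pytest.approx(0.0055746, abs=1e-6)

    def test_discordant_cancellation(self):
        p, z = stouffer_combine(0.05, +1, 0.05, -1)
        assert z == 0.0 and p == 1.0

    def test_symmetry_in_arguments(self):
        assert stouffer_combine(0.02, +1, 0.3, -1) == stouffer_combine(
            0.3, -1, 0.02, +1
        )

    def test_out_of_range_p_rejected(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                stouffer_combine(bad, 1, 0.5, 1)


class TestLmrCutoff:
    def null(self, values):
        return NullDistribution("lmr", np.asarray(values, float), 1, "exhaustive", 0)

    def test_symmetric_five_point_null(self):
        # linear-interpolation percentiles of {-2,-1,0,1,2} are -1.9, 1.9
        assert lmr_cutoff(self.null([-2, -1, 0, 1, 2])) == pytest.approx(1.9)

    def test_all_zero_null(self):
        assert lmr_cutoff(self.null([0.0] * 10)) == 0.0

    def test_homogeneity(self):
        values = np.random.default_rng(0).normal(size=200)
        assert lmr_cutoff(self.null(values * 3.0)) == pytest.approx(
            3.0 * lmr_cutoff(self.null(values))
        )


class TestBuildNull:
    def test_exhaustive_mode_on_3v3(self, oracle_fixture, oracle_normalized):
        cm, _ = oracle_fixture
        contrast = ContrastSpec.from_groups(cm.groups, "grpA", "grpB", seed=3)
        null_t, null_lmr = build_null(oracle_normalized, contrast)
        # 20 distinct splits minus the observed labeling and its mirror
        assert null_t.scheme == "exhaustive"
        assert null_t.n_resamples_effective == 18
        assert len(null_t) == 6 * 18
        assert len(null_lmr) == len(null_t)

    def test_same_seed_reproducible_in_random_mode(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.normal(size=(40, 14)), columns=[f"s{i}" for i in range(14)]
        )
        m = NormalizedMatrix(df, ("cpm", "log2", "quantile"))
        groups = {f"s{i}": ("a" if i < 7 else "b") for i in range(14)}
        contrast = ContrastSpec.from_groups(
            groups, "a", "b", n_resamples=100, seed=42
        )
        n1t, n1l = build_null(m, contrast)
        n2t, n2l = build_null(m, contrast)
        assert n1t.scheme == "random"  # C(14,7) = 3432 > 100
        np.testing.assert_array_equal(n1t.values, n2t.values)
        np.testing.assert_array_equal(n1l.values, n2l.values)

    def test_null_median_near_zero_without_signal(self):
        medians = []
        for seed in range(5):
            spec = DesignSpec(
                n_genes=200, group_sizes={"a": 4, "b": 4}, dispersion=0.1, seed=seed
            )
            cm, _ = simulate_experiment(spec)
            m = normalize_full(cm)
            contrast = ContrastSpec.from_groups(cm.groups, "b", "a", seed=seed)
            null_t, _ = build_null(m, contrast)
            medians.append(null_t.median)
        assert abs(np.mean(medians)) < 0.05


class TestCallDegs:
    def test_planted_gene_called_up(self):
        # a single planted gene with a +5 log2 effect must be called "up"
        spec = DesignSpec(
            n_genes=200,
            group_sizes={"ctrl": 5, "treat": 5},
            de_fraction=1 / 200,
            de_log2fc=5.0,
            dispersion=0.1,
            seed=3,
        )
        cm, truth = simulate_experiment(spec)
        planted = truth.index[truth.is_de][0]
        assert truth.loc[planted, "sign"] == 1  # effect lands on 'treat'
        m = normalize_full(cm)
        result = call_degs(m, ContrastSpec.from_groups(cm.groups, "treat", "ctrl", seed=3))
        assert result.statistics.loc[planted, "call"] == "up"

    def test_sample_order_within_groups_irrelevant(self, oracle_fixture, oracle_normalized):
        cm, _ = oracle_fixture
        base = ContrastSpec.from_groups(cm.groups, "grpA", "grpB", seed=1)
        shuffled = ContrastSpec(
            "grpA",
            "grpB",
            tuple(reversed(base.samples_a)),
            tuple(reversed(base.samples_b)),
            seed=1,
        )
        r1 = call_degs(oracle_normalized, base)
        r2 = call_degs(oracle_normalized, shuffled)
        for col in ("t", "lmr", "p_t", "p_lmr", "overall_p"):
            np.testing.assert_array_equal(
                r1.statistics[col].to_numpy(), r2.statistics[col].to_numpy()
            )
        assert r1.lmr_cutoff == r2.lmr_cutoff

    def test_calls_reproducible_from_statistics_and_cutoff(self, small_result):
        result, _ = small_result
        st = result.statistics
        selector = st["adj_p"] if result.contrast.adjust == "BH" else st["overall_p"]
        passed = (selector < result.contrast.alpha) & (
            st["lmr"].abs() > result.lmr_cutoff
        )
        expected = np.where(
            passed & (st["lmr"] > 0), "up", np.where(passed, "down", "ns")
        )
        np.testing.assert_array_equal(st["call"].to_numpy(), expected)

    def test_direction_follows_lmr_sign(self, small_result):
        result, _ = small_result
        st = result.statistics
        assert (st.loc[st["call"] == "up", "lmr"] > 0).all()
        assert (st.loc[st["call"] == "down", "lmr"] < 0).all()

    def test_missing_sample_rejected(self, oracle_normalized):
        contrast = ContrastSpec(
            "grpA", "grpB", ("grpA_1", "ghost"), ("grpB_1", "grpB_2"), seed=0
        )
        with pytest.raises(ValueError, match="ghost"):
            call_degs(oracle_normalized, contrast)


class TestPowerMonotonicity:
    def test_sensitivity_nondecreasing_in_effect_size(self):
        """Mean recall of planted genes grows with the planted |log2fc|."""
        mean_sens = []
        for lfc in (0.5, 1.0, 2.0, 3.0):
            sens = []
            for seed in range(1, 6):
                spec = DesignSpec(
                    n_genes=1000,
                    group_sizes={"a": 5, "b": 5},
                    de_fraction=0.05,
                    de_log2fc=lfc,
                    dispersion=0.1,
                    seed=seed,
                )
                cm, truth = simulate_experiment(spec)
                m = normalize_full(cm)
                res = call_degs(m, ContrastSpec.from_groups(cm.groups, "b", "a", seed=seed))
                st = res.statistics
                called = set(st.index[st["call"] != "ns"])
                true_de = set(truth.index[truth.is_de]) & set(st.index)
                sens.append(len(called & true_de) / len(true_de))
            mean_sens.append(np.mean(sens))
        inversions = [
            max(mean_sens[i] - mean_sens[i + 1], 0.0)
            for i in range(len(mean_sens) - 1)
        ]
        assert sum(1 for v in inversions if v > 0) <= 1
        assert max(inversions, default=0.0) <= 0.02


class TestAgainstIndependentOracles:
    def test_t_matches_scipy_on_random_data(self):
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            expected = sps.ttest_ind(a, b, equal_var=True).statistic
            assert compute_t(a, b) == pytest.approx(expected, rel=1e-12)

    def test_stouffer_matches_stdlib_normal(self):
        nd = NormalDist()
        rng = np.random.default_rng(4)
        for _ in range(50):
            p1, p2 = rng.uniform(1e-6, 1.0, size=2)
            s1, s2 = rng.choice([-1.0, 1.0], size=2)
            p, z = stouffer_combine(p1, s1, p2, s2)
            z_exp = (s1 * nd.inv_cdf(1 - p1 / 2) + s2 * nd.inv_cdf(1 - p2 / 2)) / math.sqrt(2)
            p_exp = 2 * (1 - nd.cdf(abs(z_exp)))
            assert z == pytest.approx(z_exp, abs=1e-10)
            assert p == pytest.approx(max(p_exp, 5e-324), abs=1e-10)
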