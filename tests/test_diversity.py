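import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from amprep import (
    AbundanceTable,
    RarefactionSpec,
    alpha_diversity,
    anova_alpha,
    expected_rarefied_richness,
    protocol_rarefaction_depth,
    rarefy_counts,
    shannon_index,
)
from amprep.diversity import DiversityError

from conftest import make_meta, milk_record


class TestRarefy:
    def test_full_depth_is_identity(self):
        counts = np.array([3, 0, 7])
        assert rarefy_counts(counts, 10, seed=1).tolist() == [3, 0, 7]

    def test_depth_one(self):
        out = rarefy_counts([4, 6, 2], 1, seed=2)
        assert out.sum() == 1
        assert (out > 0).sum() == 1

    def test_total_exact_and_elementwise_bound(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=30)
        counts[0] += 1  # ensure non-zero total
        d = int(counts.sum() // 3) or 1
        for seed in range(10):
            out = rarefy_counts(counts, d, seed=seed)
            assert out.sum() == d
            assert np.all(out <= counts)
            assert np.all(out >= 0)

    def test_depth_above_total_errors(self):
        with pytest.raises(DiversityError, match="exceeds"):
            rarefy_counts([2, 2], 5)

    def test_mean_richness_matches_hypergeometric_expectation(self):
        counts = np.array([5, 5])
        d = 2
        expected = expected_rarefied_richness(counts, d)
        assert expected == pytest.approx(14 / 9, abs=1e-12)
        n_draws = 20000
        rng = np.random.default_rng(123)
        richness = np.empty(n_draws)
        for i in range(n_draws):
            richness[i] = (rarefy_counts(counts, d, rng) > 0).sum()
        se = richness.std(ddof=1) / math.sqrt(n_draws)
        assert abs(richness.mean() - expected) <= 3 * se


class TestExpectedRichness:
    def test_full_depth_equals_observed(self):
        counts = np.array([4, 1, 0, 9])
        assert expected_rarefied_richness(counts, 14) == pytest.approx(3.0)

    def test_direct_combinatorics(self):
        # 2 * (1 - C(5,2)/C(10,2)) = 2 * (1 - 10/45)
        assert expected_rarefied_richness([5, 5], 2) == pytest.approx(2 * (1 - 10 / 45))

    def test_depth_one_is_one(self):
        assert expected_rarefied_richness([3, 9, 1], 1) == pytest.approx(1.0)

    def test_large_totals_stay_finite(self):
        counts = np.full(50, 20000)  # total 1e6
        val = expected_rarefied_richness(counts, 500)
        assert np.isfinite(val)
        assert 0 < val <= 50

    def test_bruteforce_enumeration_oracle(self):
        # exhaustive subsets on a tiny vector: counts (2,1,1), d=2
        from itertools import combinations

        counts = [2, 1, 1]
        reads = [0, 0, 1, 2]  # read -> ASV index
        total = len(reads)
        d = 2
        richness = [len({reads[i] for i in subset}) for subset in combinations(range(total), d)]
        assert expected_rarefied_richness(counts, d) == pytest.approx(np.mean(richness))


class TestAlphaDiversity:
    def test_uniform_four_asvs(self):
        res = alpha_diversity([5, 5, 5, 5], 20, seed=0)
        assert res.richness == 4
        assert res.shannon == pytest.approx(math.log(4))
        assert res.evenness == pytest.approx(1.0)

    def test_single_asv(self):
        res = alpha_diversity([9], 9, seed=0)
        assert res.shannon == 0.0
        assert res.richness == 1
        assert res.evenness is None

    def test_three_one_full_depth(self):
        res = alpha_diversity([3, 1], 4, seed=0)
        h = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert res.shannon == pytest.approx(h)
        assert res.shannon == pytest.approx(0.5623, abs=5e-5)
        assert res.evenness == pytest.approx(h / math.log(2))
        assert res.evenness == pytest.approx(0.8113, abs=5e-5)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(1, 500), min_size=2, max_size=15))
    def test_shannon_permutation_invariant_and_max_at_uniform(self, counts):
        h = shannon_index(counts)
        rng = np.random.default_rng(0)
        perm = rng.permutation(counts)
        assert shannon_index(perm) == pytest.approx(h, abs=1e-12)
        assert h <= math.log(len(counts)) + 1e-12

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(0, 300), min_size=2, max_size=20).filter(lambda v: sum(v) >= 4)
    )
    def test_evenness_in_unit_interval(self, counts):
        d = max(2, sum(counts) // 2)
        res = alpha_diversity(counts, d, seed=1)
        if res.evenness is not None:
            assert -1e-12 <= res.evenness <= 1.0 + 1e-12

    def test_evenness_one_iff_uniform(self):
        res = alpha_diversity([7, 7, 7], 21, seed=0)
        assert res.evenness == pytest.approx(1.0)
        res2 = alpha_diversity([10, 4], 14, seed=0)
        assert res2.evenness < 1.0


class TestProtocolDepth:
    def build(self, totals_by_sample):
        asvs = ["A0"]
        samples = list(totals_by_sample)
        counts = np.array([[totals_by_sample[s] for s in samples]])
        table = AbundanceTable(asvs, samples, counts)
        meta = make_meta(
            [milk_record(s, erep=i + 1) for i, s in enumerate(samples)]
        )
        return table, meta

    def test_min_policy(self):
        table, meta = self.build({"a": 302, "b": 900, "c": 5000})
        depths = protocol_rarefaction_depth(table, meta, RarefactionSpec())
        assert depths == {("P3", "V1V2"): 302}

    def test_explicit_spec_verbatim(self):
        table, meta = self.build({"a": 302, "b": 900, "c": 5000})
        spec = RarefactionSpec(
            policy="explicit",
            explicit_depths={("P3", "V1V2"): 302, ("P4", "V1V2"): 468, ("P6", "V1V2"): 1302},
        )
        depths = protocol_rarefaction_depth(table, meta, spec)
        assert depths[("P3", "V1V2")] == 302
        assert depths[("P4", "V1V2")] == 468
        assert depths[("P6", "V1V2")] == 1302

    def test_all_equal(self):
        table, meta = self.build({"a": 777, "b": 777})
        depths = protocol_rarefaction_depth(table, meta, RarefactionSpec())
        assert depths == {("P3", "V1V2"): 777}


class TestAnova:
    def test_equal_group_means(self):
        f, p = anova_alpha([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert f == 0.0
        assert p == 1.0

    def test_degenerate_zero_within_variance(self):
        with pytest.warns(UserWarning):
            f, p = anova_alpha([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert math.isinf(f)
        assert p == 0.0

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        f, p = anova_alpha(values, groups)
        ref = stats.f_oneway(values[:10], values[10:20], values[20:])
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_textbook_sums_of_squares(self):
        # brute-force SS decomposition on a small worked example
        g1, g2, g3 = [6.0, 8.0, 4.0], [5.0, 7.0, 9.0], [2.0, 4.0, 3.0]
        values = g1 + g2 + g3
        groups = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        grand = np.mean(values)
        ssb = sum(3 * (np.mean(g) - grand) ** 2 for g in (g1, g2, g3))
        ssw = sum((x - np.mean(g)) ** 2 for g in (g1, g2, g3) for x in g)
        f_expected = (ssb / 2) / (ssw / 6)
        f, p = anova_alpha(values, groups)
        assert f == pytest.approx(f_expected, rel=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=24)
        groups = np.repeat(["a", "b", "c", "d"], 6)
        f1, p1 = anova_alpha(values, groups)
        f2, p2 = anova_alpha(5.0 * values - 17.0, groups)
        assert f2 == pytest.approx(f1, rel=1e-9)
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_single_group_errors(self):
        with pytest.raises(DiversityError):
            anova_alpha([1, 2, 3], ["a", "a", "a"])
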