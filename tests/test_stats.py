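"""Statistical primitives: normalisations, paired count test, Wilcoxon, BH."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import erf

from primedchip.containers import NormalizedMatrix
from primedchip.stats import (
    add_half_min_pseudocount,
    bh_adjust,
    binomial_upper_tail,
    log2_ratio,
    paired_count_test,
    paired_count_test_matrix,
    rpkm,
    rpm,
    sqrt_pearson,
    wilcoxon_signed_rank,
    zscore_rows,
)


def norm(values, scale="RPM"):
    return NormalizedMatrix(pd.DataFrame(values, dtype=float), scale=scale)


# ---------------------------------------------------------------------------
# Normalisations
# ---------------------------------------------------------------------------

class TestNormalisations:
    def test_rpm_values(self):
        assert list(rpm(np.array([10, 90]), 100)) == [100000.0, 900000.0]

    def test_rpm_all_zero(self):
        assert list(rpm(np.zeros(3), 10)) == [0.0, 0.0, 0.0]

    def test_rpm_sums_to_million_when_column_sums_to_library(self):
        counts = np.array([10, 20, 70])
        assert rpm(counts, counts.sum()).sum() == pytest.approx(1e6)

    def test_rpm_scale_consistency(self):
        counts = np.array([3, 17, 41])
        assert np.allclose(rpm(counts * 7, 700), rpm(counts, 100))

    def test_rpm_invalid_library(self):
        with pytest.raises(ValueError):
            rpm(np.array([1]), 0)

    def test_rpkm_value(self):
        assert rpkm(np.array([10]), np.array([1000]), 10**6)[0] == pytest.approx(10.0)

    def test_rpkm_halves_when_length_doubles(self):
        a = rpkm(np.array([10]), np.array([1000]), 10**6)[0]
        b = rpkm(np.array([10]), np.array([2000]), 10**6)[0]
        assert b == pytest.approx(a / 2)

    def test_rpkm_matches_hand_formula(self):
        counts = np.array([5, 12, 0, 33])
        lengths = np.array([500, 1500, 2000, 800])
        lib = 250_000
        got = rpkm(counts, lengths, lib)
        expected = [c * 1e9 / (l * lib) for c, l in zip(counts, lengths)]
        assert np.allclose(got, expected)


class TestPseudocount:
    def test_half_positive_minimum_added(self):
        out = add_half_min_pseudocount(norm([[0, 2], [4, 8]]))
        assert out.values.to_numpy().tolist() == [[1, 3], [5, 9]]
        assert out.pseudocount == 1.0

    def test_constant_positive_matrix(self):
        out = add_half_min_pseudocount(norm([[4.0, 4.0]]))
        assert np.allclose(out.values, 6.0)

    def test_order_preserved(self):
        vals = np.array([[0.0, 5.0, 1.0, 3.0]])
        out = add_half_min_pseudocount(norm(vals)).values.to_numpy()
        assert (np.argsort(out[0]) == np.argsort(vals[0])).all()

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            add_half_min_pseudocount(norm([[0.0, 0.0]]))


class TestLog2Ratio:
    def test_equal_columns_zero(self):
        s = pd.Series([1.0, 2.0, 3.0])
        assert np.allclose(log2_ratio(s, s), 0.0)

    def test_doubling_gives_one(self):
        s = pd.Series([1.0, 2.0])
        assert np.allclose(log2_ratio(2 * s, s), 1.0)

    def test_replicates_averaged_before_ratio(self):
        num = pd.DataFrame({"a": [3.0], "b": [5.0]})
        den = pd.DataFrame({"a": [1.0], "b": [3.0]})
        assert log2_ratio(num, den)[0] == pytest.approx(1.0)  # mean 4 over mean 2

    def test_nonpositive_input_raises(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log2_ratio(pd.Series([0.0]), pd.Series([1.0]))


class TestZscoreRows:
    def test_closed_form_row(self):
        out = zscore_rows(norm([[1.0, 2.0, 3.0]])).values.to_numpy()[0]
        assert np.allclose(out, [-1.22474487, 0.0, 1.22474487])

    def test_constant_row_maps_to_zero(self):
        out = zscore_rows(norm([[5.0, 5.0, 5.0]])).values.to_numpy()[0]
        assert np.allclose(out, 0.0)

    def test_row_means_zero(self):
        rng = np.random.default_rng(0)
        out = zscore_rows(norm(rng.random((20, 6)))).values
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)


class TestSqrtPearson:
    def test_identity_gives_one(self):
        x = np.array([0.0, 1.0, 4.0, 9.0])
        assert sqrt_pearson(x, x).r == pytest.approx(1.0)

    def test_proportional_gives_one(self):
        x = np.array([1.0, 4.0, 9.0, 16.0])
        assert sqrt_pearson(x, 2.5 * x).r == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(10) * 50, rng.random(10) * 50
        sx, sy = np.sqrt(x), np.sqrt(y)
        cov = ((sx - sx.mean()) * (sy - sy.mean())).mean()
        oracle = cov / (sx.std() * sy.std())
        assert sqrt_pearson(x, y).r == pytest.approx(oracle)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            sqrt_pearson(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# Paired count test
# ---------------------------------------------------------------------------

class TestPairedCountTest:
    def test_symmetric_null_gives_large_p(self):
        res = paired_count_test([50, 60, 40], [50, 60, 40], [1e6] * 3, [1e6] * 3)
        assert res.p_value > 0.5

    def test_single_replicate_binomial_tail(self):
        # P(X >= 8 | n=10, pi=0.5) = 56/1024, by enumeration of the tail
        res = paired_count_test([8], [2], [1000], [1000])
        p_upper = sum(math.comb(10, k) for k in range(8, 11)) / 2**10
        assert p_upper == 56 / 1024
        z = sps.norm.ppf(1 - p_upper)
        expected_p = 2 * sps.norm.cdf(-abs(z))
        assert res.p_value == pytest.approx(expected_p, rel=1e-12)

    def test_two_identical_replicates_stouffer(self):
        res = paired_count_test([8, 8], [2, 2], [1000] * 2, [1000] * 2)
        z1 = sps.norm.ppf(1 - 56 / 1024)
        Z = 2 * z1 / np.sqrt(2)
        assert res.statistic == pytest.approx(Z, rel=1e-12)
        # independent erf-based normal CDF oracle
        oracle_p = 2 * 0.5 * (1 + erf(-abs(Z) / np.sqrt(2)))
        assert res.p_value == pytest.approx(oracle_p, rel=1e-9)

    def test_all_empty_replicates(self):
        res = paired_count_test([0, 0], [0, 0], [100, 100], [100, 100])
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_library_imbalance_sets_null_proportion(self):
        # counts proportional to library sizes are null: a=20 of n=30 with
        # pi = 2e6/3e6 = 2/3 is exactly the expectation
        res = paired_count_test([20], [10], [2e6], [1e6])
        assert res.p_value > 0.3

    def test_effect_is_pseudocounted_mean_rpm_ratio(self):
        res = paired_count_test([10, 20], [5, 10], [1e6, 1e6], [1e6, 1e6])
        assert res.effect == pytest.approx((15 + 3.75) / (7.5 + 3.75))

    def test_matrix_version_matches_scalar(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(40, size=(50, 3))
        b = rng.poisson(40, size=(50, 3))
        libs = np.array([9e5, 1e6, 1.1e6])
        mat = paired_count_test_matrix(a, b, libs, libs)
        for i in (0, 13, 49):
            single = paired_count_test(a[i], b[i], libs, libs)
            assert mat["statistic"].iloc[i] == pytest.approx(single.statistic)
            assert mat["p_value"].iloc[i] == pytest.approx(single.p_value)

    def test_null_p_values_near_uniform(self):
        # under the binomial null the combined p should be uniform up to
        # tail discreteness
        rng = np.random.default_rng(11)
        n = rng.poisson(200, size=(5000, 3))
        a = rng.binomial(n, 0.5)
        b = n - a
        libs = np.ones(3)
        res = paired_count_test_matrix(a, b, libs, libs)
        ks = sps.kstest(res["p_value"], "uniform").statistic
        assert ks < 0.05


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def brute_force_wilcoxon_p(d):
    """Literal 2^n sign enumeration of the signed-rank null."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([True, False], repeat=len(d))
    ]
    ws = np.array(ws)
    p_ge = (ws >= w_obs - 1e-9).mean()
    p_le = (ws <= w_obs + 1e-9).mean()
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxonSignedRank:
    def test_identical_pairs_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_all_positive_three(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(2 / 8)

    def test_mixed_signs_three(self):
        res = wilcoxon_signed_rank([1.0, -2.0, 3.0])
        assert res.statistic == 4.0
        assert res.p_value == pytest.approx(0.75)  # 2 * min(3/8, 6/8)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_brute_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        d = rng.normal(size=n)
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d), rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy_cross_check(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(size=12)
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("n", [20, 23, 25])
    def test_normal_approximation_close_to_exact(self, n, monkeypatch):
        import primedchip.stats as stats_mod

        rng = np.random.default_rng(n)
        d = rng.normal(0.3, 1.0, n)  # continuous draws -> tie-free
        exact = wilcoxon_signed_rank(d).p_value  # n <= 25 -> exact path
        monkeypatch.setattr(stats_mod, "EXACT_WILCOXON_MAX_N", 0)
        approx = wilcoxon_signed_rank(d).p_value
        assert abs(approx - exact) < 0.02

    def test_tied_differences_use_midrank_enumeration(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 2.0, -3.0, 4.0])
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d), rel=1e-12)

    def test_all_equal_differences_give_sign_test_p(self):
        # five identical positive differences: P = 2 * 1/2^5
        res = wilcoxon_signed_rank(np.ones(5))
        assert res.p_value == pytest.approx(2 / 32)

    def test_large_tied_sample_uses_corrected_normal_approximation(self):
        rng = np.random.default_rng(42)
        d = rng.integers(-5, 6, 40).astype(float)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_differences(self):
        res = wilcoxon_signed_rank([0.0, 0.0], [0.0, 0.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Hand step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_sorted_q_non_decreasing(self):
        rng = np.random.default_rng(2)
        q = bh_adjust(rng.random(100))
        assert (np.diff(np.sort(q)) >= -1e-12).all()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p))

    @given(
        st.lists(st.floats(0.001, 1), min_size=2, max_size=30),
        st.data(),
    )
    @settings(deadline=None, max_examples=30)
    def test_lowering_a_p_never_raises_q(self, p, data):
        i = data.draw(st.integers(0, len(p) - 1))
        lowered = list(p)
        lowered[i] = lowered[i] / 2
        q_before = bh_adjust(p)
        q_after = bh_adjust(lowered)
        assert (q_after <= q_before + 1e-12).all()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def test_binomial_upper_tail_includes_boundary():
    # P(X >= 0) = 1 and a simple exact value
    assert binomial_upper_tail(0, 10, 0.5) == pytest.approx(1.0)
    assert binomial_upper_tail(10, 10, 0.5) == pytest.approx(0.5**10)
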