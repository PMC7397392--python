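import math
from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from docmark import stats


# ---------------------------------------------------------------- oracles
def wilcoxon_enumeration_oracle(values, reference):
    """Literal enumeration of all 2^m sign patterns of the observed ranks."""
    d = np.asarray(values, dtype=float) - reference
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product((False, True), repeat=d.size)
    ]
    sums = np.array(sums)
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def mann_whitney_enumeration_oracle(a, b):
    """Literal enumeration of all C(n+m, n) group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array([
        ranks[list(idx)].sum() - n * (n + 1) / 2
        for idx in combinations(range(ranks.size), n)
    ])
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def bf10_grid_oracle(t, n, r=stats.DEFAULT_PRIOR_SCALE, n_grid=200001, half_width=30.0):
    """Fine trapezoid quadrature over the effect-size prior."""
    delta = np.linspace(-half_width, half_width, n_grid)
    integrand = sps.nct.pdf(t, n - 1, math.sqrt(n) * delta) * sps.cauchy.pdf(delta, 0, r)
    return np.trapezoid(integrand, delta) / sps.t.pdf(t, n - 1)


def spearman_rank_oracle(x, y):
    """Average ranks computed by hand, then the Pearson formula."""
    def avg_rank(v):
        v = np.asarray(v, float)
        out = np.empty(v.size)
        order = np.sort(v)
        for i, val in enumerate(v):
            idx = np.flatnonzero(order == val) + 1
            out[i] = idx.mean()
        return out

    rx, ry = avg_rank(x), avg_rank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


# ---------------------------------------------------------------- outcome
class TestClassifyOutcome:
    @pytest.mark.parametrize("gose,label", [
        (1, stats.OUTCOME_NEGATIVE), (2, stats.OUTCOME_NEGATIVE),
        (3, stats.OUTCOME_POSITIVE), (8, stats.OUTCOME_POSITIVE),
    ])
    def test_threshold_rule(self, gose, label):
        assert stats.classify_outcome(gose).label == label

    @pytest.mark.parametrize("gose", [0, 9, -1])
    def test_out_of_range_rejected(self, gose):
        with pytest.raises(ValueError):
            stats.classify_outcome(gose)

    def test_partitions_any_gose_column(self):
        labels = [stats.classify_outcome(g).label for g in range(1, 9)]
        assert all(l in (stats.OUTCOME_NEGATIVE, stats.OUTCOME_POSITIVE) for l in labels)


class TestHealthyReference:
    def test_odd_and_even_conventions(self):
        assert stats.healthy_reference([0.1, 0.3, 0.5]) == pytest.approx(0.3)
        assert stats.healthy_reference([0.1, 0.3]) == pytest.approx(0.2)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(0.3, 0.2, 35)
        assert stats.healthy_reference(deltas) == pytest.approx(np.sort(deltas)[17])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.healthy_reference([])


# ---------------------------------------------------------------- wilcoxon
class TestWilcoxon:
    def test_frozen_enumeration_example(self):
        assert stats.wilcoxon_one_sample([0.1, 0.2, 0.3], 0, "exact").p == pytest.approx(0.25)

    def test_symmetric_sample_gives_p_one(self):
        res = stats.wilcoxon_one_sample([-1.0, 1.0], 0, "exact")
        assert res.p == pytest.approx(1.0)
        assert res.statistic == pytest.approx(1.5)  # midpoint of [0, 3]

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_one_sample([0.5, 0.5], 0.5)

    def test_reproduces_published_small_sample_z(self):
        """n=5, every delta below the reference: the SPSS-convention Z."""
        res = stats.wilcoxon_one_sample([-0.1, -0.2, -0.3, -0.4, -0.5], 0.0,
                                        "asymptotic", continuity=False)
        assert res.z_approx == pytest.approx(-2.023, abs=5e-4)
        assert res.p == pytest.approx(0.043, abs=5e-4)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=10))
    def test_exact_matches_enumeration_oracle(self, values):
        vals = np.array(values, float)
        if np.all(vals == 0):
            return
        got = stats.wilcoxon_one_sample(vals, 0.0, "exact").p
        assert got == pytest.approx(wilcoxon_enumeration_oracle(vals, 0.0), abs=1e-12)

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.3, 1.0, 12)
        got = stats.wilcoxon_one_sample(x, 0.0, "exact")
        ref = sps.wilcoxon(x, alternative="two-sided", method="exact")
        assert got.p == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_asymptotic_close_to_exact_at_n20(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.2, 1.0, 20)
        p_exact = stats.wilcoxon_one_sample(x, 0.0, "exact").p
        p_asym = stats.wilcoxon_one_sample(x, 0.0, "asymptotic").p
        assert abs(p_exact - p_asym) < 0.02


# ---------------------------------------------------------------- mann-whitney
class TestMannWhitney:
    def test_frozen_enumeration_example(self):
        res = stats.mann_whitney([1, 2, 3], [4, 5, 6], "exact")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(0.1)

    def test_identical_samples_sit_at_null_center(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = stats.mann_whitney(a, a, "asymptotic")
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.z_approx == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney([], [1.0])

    def test_reproduces_published_small_sample_z(self):
        """U=7 with n=10 vs 5 gives the SPSS-convention Z of -2.205."""
        a = list(range(10))
        b = [-1.0, -0.5, 0.5, 1.5, 3.5]  # places 0+0+1+2+4 a-values below b: U_b = 7
        res = stats.mann_whitney(a, b, "asymptotic", continuity=False)
        u_b = 50 - res.statistic
        z_b = (u_b - 25) / math.sqrt(10 * 5 * 16 / 12)
        assert u_b == pytest.approx(7.0)
        assert z_b == pytest.approx(-2.205, abs=5e-4)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(-4, 4), min_size=1, max_size=6),
        st.lists(st.integers(-4, 4), min_size=1, max_size=6),
    )
    def test_exact_matches_enumeration_oracle(self, a, b):
        got = stats.mann_whitney(a, b, "exact").p
        assert got == pytest.approx(mann_whitney_enumeration_oracle(a, b), abs=1e-12)

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        got = stats.mann_whitney(a, b, "exact")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert got.p == pytest.approx(ref.pvalue, abs=1e-12)


# ---------------------------------------------------------------- paired t
class TestPairedT:
    def test_zero_mean_difference(self):
        t, df, p = stats.paired_t([1, 0, 1, 0], [0, 1, 0, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 3

    def test_constant_nonzero_difference_is_zero_variance(self):
        with pytest.raises(ValueError, match="variance"):
            stats.paired_t([2, 3, 4], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stats.paired_t([1, 2], [1, 2, 3])

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0.5, 1, 25), rng.normal(0, 1, 25)
        t, df, p = stats.paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


# ---------------------------------------------------------------- bayes factor
class TestJzsBf10:
    def test_null_t_favors_null(self):
        assert stats.jzs_bf10(0.0, 35).bf10 < 1.0

    def test_monotone_in_abs_t_and_sign_invariant(self):
        bfs = [stats.jzs_bf10(t, 20).bf10 for t in (0.5, 1.0, 2.0, 4.0)]
        assert bfs == sorted(bfs)
        assert stats.jzs_bf10(-2.0, 20).bf10 == pytest.approx(
            stats.jzs_bf10(2.0, 20).bf10, rel=1e-9
        )

    def test_matches_fine_grid_quadrature_oracle(self):
        got = stats.jzs_bf10(2.0, 20).bf10
        assert got == pytest.approx(bf10_grid_oracle(2.0, 20), rel=1e-4)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        got = stats.jzs_bf10(2.5, 30).bf10
        assert got == pytest.approx(float(pg.bayesfactor_ttest(2.5, 30, paired=True)), rel=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.jzs_bf10(float("nan"), 10)
        with pytest.raises(ValueError):
            stats.jzs_bf10(1.0, 1)


# ---------------------------------------------------------------- spearman
class TestSpearman:
    def test_perfect_monotone(self):
        x = list(range(1, 11))
        assert stats.spearman(x, x)[0] == pytest.approx(1.0)
        assert stats.spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, 15).astype(float)
        y = x + rng.integers(0, 3, 15)
        rho, _ = stats.spearman(x, y)
        assert rho == pytest.approx(spearman_rank_oracle(x, y), abs=1e-12)

    def test_matches_scipy_including_one_sided(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=14), rng.normal(size=14)
        y = y + 0.5 * x
        rho, p1 = stats.spearman(x, y, sided="one")
        ref = sps.spearmanr(x, y, alternative="greater")
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p1 == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            stats.spearman([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------- report
class TestPrognosticReport:
    def test_structure_and_identical_subgroups(self):
        healthy = np.linspace(0.1, 0.5, 9)
        pat = np.array([0.3, 0.3, 0.3, 0.1, 0.2])
        gose = [5, 6, 7, 1, 2]
        rep = stats.prognostic_report(healthy, pat, gose)
        assert rep["healthy_median"] == pytest.approx(0.3)
        assert rep["subgroups"][stats.OUTCOME_POSITIVE]["n"] == 3
        assert rep["subgroups"][stats.OUTCOME_NEGATIVE]["n"] == 2
        assert rep["mann_whitney_pos_vs_neg"] is not None

    def test_mann_whitney_z_zero_for_identical_values(self):
        rep = stats.prognostic_report(
            [0.1, 0.2, 0.9], [0.4, 0.4, 0.4, 0.4], [5, 6, 1, 2]
        )
        assert rep["mann_whitney_pos_vs_neg"].z_approx == pytest.approx(0.0)

    def test_missing_subgroup_flagged_not_fatal(self):
        rep = stats.prognostic_report([0.1, 0.2, 0.3], [0.4, 0.5], [5, 6])
        assert rep["mann_whitney_pos_vs_neg"] is None
        assert any("empty" in f for f in rep["flags"])

    def test_wilcoxon_degenerate_subgroup_flagged(self):
        # every positive delta equals the healthy median -> nothing to rank
        rep = stats.prognostic_report([0.4], [0.4, 0.4, 0.5], [5, 6, 1])
        assert rep["subgroups"][stats.OUTCOME_POSITIVE]["wilcoxon_vs_healthy_median"] is None
        assert any("outcome_positive" in f for f in rep["flags"])
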