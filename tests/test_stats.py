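from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from musclempi.stats import (
    bonferroni,
    friedman,
    kruskal_with_posthoc,
    spearman,
    wilcoxon_signed_rank,
)


def enumerate_signed_rank_p(d):
    """Exact two-sided p by enumerating every sign assignment of |d|."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=len(d))
    ]
    vs = np.array(vs, dtype=float)
    p_low = np.mean(vs <= v_obs)
    p_high = np.mean(vs >= v_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_all_negative_differences_give_v_zero(self):
        x = np.arange(5.0)
        res = wilcoxon_signed_rank(x, x + 1.0)
        assert res.statistic == 0.0

    def test_hand_enumerated_ranks(self):
        # d = {+1, -2, +3} -> ranks {1, 2, 3}, V = 1 + 3 = 4
        res = wilcoxon_signed_rank(
            np.array([1.0, 0.0, 3.0]), np.array([0.0, 2.0, 0.0])
        )
        assert res.statistic == 4.0

    def test_zero_differences_dropped_and_degenerate_case_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank(np.ones(4), np.ones(4))
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("n", range(3, 11))
    def test_exact_p_matches_sign_enumeration(self, n, rng):
        for _ in range(5):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.3, 1, n)
            res = wilcoxon_signed_rank(x, y)
            assert res.p_value == pytest.approx(enumerate_signed_rank_p(x - y))

    def test_affine_invariance(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(3.0 * x + 7.0, 3.0 * y + 7.0)
        assert a.statistic == b.statistic and a.p_value == pytest.approx(b.p_value)


class TestFriedman:
    def test_identical_conditions_are_null(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = friedman(m)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.df == 2

    def test_statistic_matches_rank_formula_for_untied_data(self, rng):
        n, k = 11, 3
        m = rng.normal(size=(n, k))
        res = friedman(m)
        ranks = sps.rankdata(m, axis=1)
        rj = ranks.sum(axis=0)
        expected = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        assert res.statistic == pytest.approx(expected)

    def test_consistent_ordering_gives_maximal_statistic(self):
        n, k = 11, 3
        m = np.add.outer(np.zeros(n), np.arange(k, dtype=float))
        m += np.arange(n)[:, None]  # distinct rows, same within-row order
        res = friedman(m)
        # maximal chi-squared: every subject ranks the conditions identically
        assert res.statistic == pytest.approx(n * (k - 1))

    def test_condition_relabelling_invariance(self, rng):
        m = rng.normal(size=(8, 4))
        perm = [2, 0, 3, 1]
        assert friedman(m).statistic == pytest.approx(friedman(m[:, perm]).statistic)

    def test_two_conditions_redirects_to_paired_test(self):
        with pytest.raises(ValueError, match="wilcoxon"):
            friedman(np.zeros((5, 2)))


class TestSpearman:
    def test_perfect_monotone_association(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, x).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_formula(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        y = rng.normal(size=7).round(0)  # induce ties in y too
        if np.unique(y).size == 1:
            y[0] += 1.0
        rho = spearman(x, y).statistic
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert spearman(np.exp(x), y**3).statistic == pytest.approx(
            spearman(x, y).statistic
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))


class TestKruskalPosthoc:
    def test_identical_groups_are_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        omnibus, posthoc = kruskal_with_posthoc([g, g, g])
        assert omnibus.p_value > 0.9
        assert all(ph["p_bonferroni"] > 0.9 for ph in posthoc)

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.04, 3) == pytest.approx(0.12)
        assert bonferroni(0.6, 3) == 1.0

    def test_separated_imaging_rate_group_is_flagged_against_both_others(self, rng):
        # relative-rate regime: imaging rates ~2.3%/yr, clinical rates mostly 0
        mpi = rng.lognormal(np.log(2.3), 0.8, size=35)
        mrcs = np.where(rng.uniform(size=35) < 0.7, 0.0, rng.normal(0, 1.0, 35))
        mfm = np.where(rng.uniform(size=35) < 0.7, 0.0, rng.normal(0, 1.2, 35))
        omnibus, posthoc = kruskal_with_posthoc(
            [mpi, mrcs, mfm], labels=["mpi", "mrcs", "mfm"]
        )
        assert omnibus.p_value < 0.05
        flagged = {
            frozenset(ph["pair"]) for ph in posthoc if ph["p_bonferroni"] < 0.05
        }
        assert frozenset(("mpi", "mrcs")) in flagged
        assert frozenset(("mpi", "mfm")) in flagged

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(i, 1, 10) for i in range(3)]
        a, _ = kruskal_with_posthoc(groups)
        b, _ = kruskal_with_posthoc([np.exp(g) for g in groups])
        assert a.statistic == pytest.approx(b.statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_with_posthoc([[1.0, 2.0], [3.0]])
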