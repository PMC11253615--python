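from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from guildscope.core_io import ValidationError
from guildscope.group_stats import (
    bh_adjust,
    fisher_exact_2x2,
    kruskal_dunn_cld,
    mann_whitney,
    partial_spearman,
)


# ---------------------------------------------------------------------------
# BH


class TestBH:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# Fisher


def _fisher_enumeration_oracle(a, b, c, d):
    """Sum P(table) over all same-margin tables with P <= P(observed)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, row1, col1)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestFisher:
    def test_butyrate_carrier_table(self):
        # 14/34 vs 2/20 carriers
        _, p = fisher_exact_2x2([[14, 20], [2, 18]])
        assert round(p, 3) == 0.029

    def test_empty_column(self):
        with pytest.warns(UserWarning):
            _, p = fisher_exact_2x2([[0, 5], [0, 7]])
        assert p == 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            t = rng.integers(0, 13, (2, 2))
            if min(t.sum(0).min(), t.sum(1).min()) == 0:
                continue
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(stats.fisher_exact(t)[1], abs=1e-10)

    def test_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 13, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(
                _fisher_enumeration_oracle(int(a), int(b), int(c), int(d)),
                abs=1e-12,
            )

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, 2], [3, -1]])
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1.5, 2], [3, 1]])


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        u, p = mann_whitney([1, 1, 2], [2, 1, 1])
        assert p == 1.0

    def test_fully_separated_exact(self):
        u, p = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_u_plus_u_prime(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=9)
        u, _ = mann_whitney(x, y)
        u2, _ = mann_whitney(y, x)
        assert u + u2 == pytest.approx(6 * 9)

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=5), rng.normal(size=6)
        _, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn + letters


class TestKruskalDunnCld:
    def test_null_groups_share_letter(self):
        rng = np.random.default_rng(5)
        share = 0
        n_rep = 200
        for _ in range(n_rep):
            values = rng.normal(size=40)
            groups = np.repeat(list("abcd"), 10)
            res = kruskal_dunn_cld(values, groups)
            letters = set(res.letters.values())
            if letters == {"a"}:
                share += 1
        assert share >= 0.9 * n_rep

    def test_three_separated_groups_all_letters_differ(self):
        # n = 10 per group: every Dunn pair reaches BH-adjusted p < 0.05
        values = np.concatenate([
            np.arange(1, 11), np.arange(101, 111), np.arange(201, 211)
        ]).astype(float)
        groups = np.repeat(["a", "b", "c"], 10)
        res = kruskal_dunn_cld(values, groups)
        assert np.all(res.dunn_p_adjusted < 0.05)
        lets = [res.letters[g] for g in ("a", "b", "c")]
        for la, lb in combinations(lets, 2):
            assert not (set(la) & set(lb))

    def test_two_groups_reduce_to_single_comparison(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(size=8), rng.normal(3, 1, size=8)])
        groups = np.repeat(["x", "y"], 8)
        res = kruskal_dunn_cld(values, groups)
        assert len(res.pairs) == 1
        # direction agrees with Mann-Whitney
        u, p_mw = mann_whitney(values[:8], values[8:])
        assert (res.dunn_z[0] < 0) == (u < 32)

    def test_letters_reconstruct_significance_graph(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([
            rng.normal(0, 1, 12), rng.normal(0.5, 1, 12),
            rng.normal(3, 1, 12), rng.normal(3.2, 1, 12),
        ])
        groups = np.repeat(list("abcd"), 12)
        res = kruskal_dunn_cld(values, groups)
        for (ga, gb), pa in zip(res.pairs, res.dunn_p_adjusted):
            shares = bool(set(res.letters[ga]) & set(res.letters[gb]))
            assert shares == (pa >= 0.05)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_dunn_cld([1.0, 2.0, 3.0], ["a", "a", "b"])


# ---------------------------------------------------------------------------
# Partial Spearman


class TestPartialSpearman:
    def test_independent_covariate_close_to_plain_spearman(self):
        rng = np.random.default_rng(8)
        n = 500
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        res = partial_spearman(x, y, z)
        plain = stats.spearmanr(x, y).statistic
        assert abs(res.rho - plain) < 0.05

    def test_perfect_dependence(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        res = partial_spearman(x, x.copy(), z)
        assert res.rho == pytest.approx(1.0)

    def test_confound_removal(self):
        rng = np.random.default_rng(10)
        n = 400
        z = rng.normal(size=n)
        x = 2 * z + rng.normal(0, 0.2, n)
        y = -3 * z + rng.normal(0, 0.2, n)
        res = partial_spearman(x, y, z)
        assert abs(res.rho) < 0.2
        plain = stats.spearmanr(x, y).statistic
        assert abs(plain) > 0.9  # the confound dominates the raw correlation

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        n = 100
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        z = rng.normal(size=n)
        r1 = partial_spearman(x, y, z)
        r2 = partial_spearman(np.exp(x), y**3, 2 * z + 5)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_missing_values_pairwise_complete(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        z = rng.normal(size=50)
        x2 = x.copy()
        x2[:5] = np.nan
        res = partial_spearman(x2, y, z)
        assert res.n == 45

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            partial_spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
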