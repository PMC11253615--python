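"""Group-difference and correlation statistics.

Kruskal-Wallis with Dunn's post hoc and compact letter displays,
Mann-Whitney (exact for small samples), Fisher's exact 2x2 with the
minimum-likelihood two-sided convention, age-adjusted partial Spearman
correlation, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from guildscope.core_io import ValidationError


# ---------------------------------------------------------------------------
# BH adjustment


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn + compact letters


@dataclass(frozen=True)
class GroupTestResult:
    variable: str
    h_statistic: float
    p: float
    pairs: tuple[tuple[str, str], ...]
    dunn_z: np.ndarray
    dunn_p: np.ndarray
    dunn_p_adjusted: np.ndarray
    letters: dict[str, str]
    group_medians: dict[str, float]


def kruskal_dunn_cld(values, groups, alpha: float = 0.05, variable: str = "") -> GroupTestResult:
    """Kruskal-Wallis test followed by Dunn's post hoc with BH and letters.

    Dunn z-statistics are tie-corrected differences of mean ranks; BH runs
    across the pairwise family.  Compact letters are assigned with the
    insert-and-absorb algorithm so that two groups share at least one
    letter iff their adjusted p >= ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    split = {g: values[groups == g] for g in levels}
    for g, v in split.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")

    h, p_kw = stats.kruskal(*(split[g] for g in levels))

    n = values.size
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))

    pairs, zs, ps = [], [], []
    for a, b in combinations(levels, 2):
        na, nb = split[a].size, split[b].size
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        pairs.append((a, b))
        zs.append(z)
        ps.append(2 * stats.norm.sf(abs(z)) if se > 0 else 1.0)
    p_adj = bh_adjust(ps)

    significant = {
        pair for pair, pa in zip(pairs, p_adj) if pa < alpha
    }
    letters = _compact_letters(levels, significant)
    return GroupTestResult(
        variable,
        float(h),
        float(p_kw),
        tuple(pairs),
        np.asarray(zs),
        np.asarray(ps),
        p_adj,
        letters,
        {g: float(np.median(split[g])) for g in levels},
    )


def _compact_letters(levels: list[str], significant: set) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups share a letter iff they are NOT significantly different.
    """
    sig = {frozenset(p) for p in significant}
    # start with one column containing every group
    columns: list[set[str]] = [set(levels)]
    for pair in sorted(sig, key=lambda s: sorted(s)):
        a, b = sorted(pair)
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb columns that are subsets of another
        columns = []
        for col in new_columns:
            if any(col < other for other in new_columns if other is not col):
                continue
            if col in columns:
                continue
            columns.append(col)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in levels}
    for k, col in enumerate(columns):
        for g in levels:
            if g in col:
                letters[g] += alphabet[k % 26]
    return letters


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney(x, y, max_exact_tables: int = 200_000) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration of label assignments (tie-safe) when the number
    of assignments is small enough — covering min(n) <= 8 at moderate total
    size — and the tie-corrected normal approximation otherwise.  Returns
    ``(U, p)`` with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    if comb(nx + ny, min(nx, ny)) <= max_exact_tables:
        center = nx * ny / 2.0
        dev_obs = abs(u - center)
        hits = total = 0
        for idx in combinations(range(nx + ny), nx):
            u_perm = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            if abs(u_perm - center) >= dev_obs - 1e-9:
                hits += 1
            total += 1
        return u, hits / total

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose likelihood does not exceed the observed
    table's (the minimum-likelihood convention, as in R).  Returns
    ``(sample_odds_ratio, p)``.  A zero margin yields p = 1 by convention.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValidationError("table must be 2x2 nonnegative integers")
    a, b, c, d = (int(v) for v in t.ravel())
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if min(row1, col1, n - row1, n - col1) == 0 or n == 0:
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention")
        odds = _sample_odds_ratio(a, b, c, d)
        return odds, 1.0
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return _sample_odds_ratio(a, b, c, d), min(p, 1.0)


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# Partial Spearman


@dataclass(frozen=True)
class PartialCorrResult:
    rho: float
    p: float
    n: int
    p_adjusted: float | None = None


def partial_spearman(x, y, z) -> PartialCorrResult:
    """Spearman correlation of x and y adjusted for z.

    Ranks all three variables on pairwise-complete observations, partials
    out z via Pearson correlations of the ranks, and tests with the t
    approximation at df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    n = x.size
    if n < 4:
        raise ValidationError("partial Spearman requires n >= 4 complete cases")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise ValidationError(f"{name} is constant")
    rx, ry, rz = stats.rankdata(x), stats.rankdata(y), stats.rankdata(z)
    r = np.corrcoef(np.vstack([rx, ry, rz]))
    r_xy, r_xz, r_yz = r[0, 1], r[0, 2], r[1, 2]
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        raise ValidationError("z fully determines x or y ranks")
    rho = float(np.clip((r_xy - r_xz * r_yz) / denom, -1.0, 1.0))
    if abs(rho) >= 1.0:
        return PartialCorrResult(rho, 0.0, n)
    t = rho * np.sqrt((n - 3) / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 3))
    return PartialCorrResult(rho, p, n)
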