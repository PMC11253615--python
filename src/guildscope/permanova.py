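"""Permutational multivariate ANOVA on distance matrices.

Single-factor tests, marginal tests (each term adjusted for the others,
free permutation of rows), and pairwise group comparisons with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from guildscope.core_io import ValidationError
from guildscope.group_stats import bh_adjust
from guildscope.transforms_distance import DistanceMatrix, _gower_center

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class PermanovaResult:
    term: str
    df_model: int
    df_resid: int
    ss_model: float
    ss_total: float
    r_squared: float
    pseudo_f: float
    p: float
    n_permutations: int
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "df": self.df_model,
            "SS": self.ss_model,
            "R2": self.r_squared,
            "F": self.pseudo_f,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "n_permutations": self.n_permutations,
        }


def _design_matrix(labels) -> tuple[np.ndarray, int]:
    """Column space for one term: indicators for a factor, the vector itself
    for a numeric covariate. Returns (columns, df)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "fiu" and np.unique(arr).size > max(2, arr.size // 3):
        col = arr.astype(float).reshape(-1, 1)
        return col - col.mean(), 1
    levels, codes = np.unique(arr.astype(str), return_inverse=True)
    if levels.size < 2:
        raise ValidationError("factor needs at least 2 levels")
    counts = np.bincount(codes)
    if np.any(counts < 2):
        lvl = levels[np.argmin(counts)]
        raise ValidationError(f"group {lvl!r} has fewer than 2 samples")
    ind = np.eye(levels.size)[codes]
    return ind - ind.mean(axis=0), levels.size - 1


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of [1, x]; rank via SVD."""
    n = x.shape[0]
    xc = np.column_stack([np.ones(n), x])
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_TOL))
    u = u[:, :rank]
    return u @ u.T, rank


def _gower(d: DistanceMatrix) -> np.ndarray:
    return _gower_center(-0.5 * d.values**2)


def permanova_single(
    d: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    term: str = "term",
) -> PermanovaResult:
    """One-term PERMANOVA with free permutation of samples.

    ``labels`` is a factor (>= 2 levels, each n >= 2) or a numeric
    covariate aligned to ``d``.  p is the inclusive permutation p-value
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != d.n:
        raise ValidationError("labels not aligned to distance matrix")
    x, df_model = _design_matrix(labels)
    g = _gower(d)
    hat, rank = _hat(x)
    df_model = rank - 1
    if df_model < 1:
        raise ValidationError("design has no model degrees of freedom")
    n = d.n
    df_resid = n - rank
    ss_total = float(np.trace(g))
    ss_model = float(np.sum(hat * g))  # trace(H G) = trace(H G H), H idempotent
    ss_resid = ss_total - ss_model
    f_obs = (ss_model / df_model) / (ss_resid / df_resid)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssm = float(np.sum(hat * gp))
        f_perm = (ssm / df_model) / ((ss_total - ssm) / df_resid)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        term,
        df_model,
        df_resid,
        ss_model,
        ss_total,
        ss_model / ss_total if ss_total > 0 else 0.0,
        f_obs,
        p,
        n_permutations,
    )


def permanova_marginal(
    d: DistanceMatrix,
    terms: dict,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> dict[str, PermanovaResult]:
    """Marginal (type-III style) PERMANOVA over several terms.

    SS(term) = SS(full) - SS(full minus term); each term's pseudo-F uses
    the full model's residual.  Rows are permuted freely (adonis2-style
    ``by = "margin"`` default scheme).  Collinear copies of a term yield
    zero marginal SS rather than an error.
    """
    names = list(terms)
    if not names:
        raise ValidationError("no terms supplied")
    cols: dict[str, np.ndarray] = {}
    for name in names:
        x, _ = _design_matrix(np.asarray(terms[name]))
        if x.shape[0] != d.n:
            raise ValidationError(f"term {name!r} not aligned to distance matrix")
        cols[name] = x

    g = _gower(d)
    n = d.n
    ss_total = float(np.trace(g))

    def model_ss(gm: np.ndarray, include: list[str]) -> tuple[float, int]:
        x = np.hstack([cols[t] for t in include])
        hat, rank = _hat(x)
        return float(np.sum(hat * gm)), rank

    ss_full, rank_full = model_ss(g, names)
    df_resid = n - rank_full
    if df_resid < 1:
        raise ValidationError("saturated design: no residual degrees of freedom")
    ss_resid = ss_total - ss_full

    obs: dict[str, tuple[float, int, float]] = {}
    for name in names:
        others = [t for t in names if t != name]
        if others:
            ss_red, rank_red = model_ss(g, others)
        else:
            ss_red, rank_red = 0.0, 1
        ss_term = max(ss_full - ss_red, 0.0)
        df_term = max(rank_full - rank_red, 0)
        f_term = (
            (ss_term / df_term) / (ss_resid / df_resid) if df_term > 0 else 0.0
        )
        obs[name] = (ss_term, df_term, f_term)

    rng = np.random.default_rng(seed)
    hits = {name: 0 for name in names}
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssf, _ = model_ss(gp, names)
        ssr = ss_total - ssf
        for name in names:
            ss_term, df_term, f_obs = obs[name]
            if df_term == 0:
                continue
            others = [t for t in names if t != name]
            ss_red = model_ss(gp, others)[0] if others else 0.0
            f_perm = (max(ssf - ss_red, 0.0) / df_term) / (ssr / df_resid)
            if f_perm >= f_obs - 1e-12:
                hits[name] += 1
    results = {}
    for name in names:
        ss_term, df_term, f_term = obs[name]
        p = (1 + hits[name]) / (1 + n_permutations) if df_term > 0 else 1.0
        results[name] = PermanovaResult(
            name,
            df_term,
            df_resid,
            ss_term,
            ss_total,
            ss_term / ss_total if ss_total > 0 else 0.0,
            f_term,
            p,
            n_permutations,
        )
    return results


def pairwise_permanova(
    d: DistanceMatrix,
    group,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> list[PermanovaResult]:
    """All pairwise single-factor PERMANOVAs with BH-adjusted p-values."""
    group = np.asarray(group).astype(str)
    if group.shape[0] != d.n:
        raise ValidationError("labels not aligned to distance matrix")
    levels = list(pd.unique(group))
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    results = []
    for a, b in combinations(levels, 2):
        mask = np.isin(group, [a, b])
        ids = [d.ids[i] for i in np.flatnonzero(mask)]
        sub = d.subset(ids)
        res = permanova_single(
            sub,
            group[mask],
            n_permutations=n_permutations,
            seed=rng,
            term=f"{a} vs {b}",
        )
        results.append(res)
    adjusted = bh_adjust([r.p for r in results])
    return [
        PermanovaResult(
            r.term,
            r.df_model,
            r.df_resid,
            r.ss_model,
            r.ss_total,
            r.r_squared,
            r.pseudo_f,
            r.p,
            r.n_permutations,
            p_adjusted=float(pa),
        )
        for r, pa in zip(results, adjusted)
    ]
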