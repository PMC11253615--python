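"""Compositional co-abundance correlation and network construction.

SparCC-style estimation: per inner iteration, per-sample fractions are
drawn from Dirichlet(counts + 1); pairwise log-ratio variances t_ij are
converted to basis variances under the sparse-correlation approximation;
strongly correlated pairs are iteratively excluded from the basis-variance
system; the final correlation is the elementwise median across inner
iterations.  Significance comes from a permutation null that shuffles each
genome independently across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from guildscope.core_io import AbundanceMatrix, ValidationError

logger = logging.getLogger("guildscope")

_OMEGA_FLOOR = 1e-12


@dataclass(frozen=True)
class SparccResult:
    genome_ids: tuple[str, ...]
    rho: np.ndarray  # symmetric, unit diagonal, clamped to [-1, 1]
    t: np.ndarray  # median log-ratio variance matrix
    omega: np.ndarray  # median basis variances
    excluded_pairs: tuple[tuple[int, int], ...] = ()

    @property
    def n(self) -> int:
        return len(self.genome_ids)


@dataclass(frozen=True)
class Edge:
    genome_a: str
    genome_b: str
    rho: float
    p: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho >= 0 else "negative"


@dataclass(frozen=True)
class EdgeList:
    genome_ids: tuple[str, ...]
    edges: tuple[Edge, ...]
    edge_p: float

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.genome_a, e.genome_b, e.rho, e.p, e.sign) for e in self.edges],
            columns=["source", "target", "rho", "p", "sign"],
        )


def _as_counts(m: AbundanceMatrix, pseudo_depth: int = 50_000) -> np.ndarray:
    if m.mode == "counts":
        return m.values
    warnings.warn(
        "sparcc received relative abundances; scaling to pseudo-counts "
        f"at depth {pseudo_depth}"
    )
    return np.round(m.values * pseudo_depth)


def _logratio_variance(logf: np.ndarray) -> np.ndarray:
    """t_ij = var over samples of log(x_i / x_j); logf is samples x genomes."""
    v = logf.var(axis=0, ddof=1)
    cov = np.cov(logf, rowvar=False)
    t = v[:, None] + v[None, :] - 2 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def _basis_variances(t: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve (D-2) w_i + sum_j w_j = sum_j t_ij under the sparsity assumption,
    dropping excluded pairs from both sides."""
    d = t.shape[0]
    m = np.ones((d, d))
    np.fill_diagonal(m, d - 1)
    t_eff = t.copy()
    for i, j in excluded:
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_eff[i, j] = t_eff[j, i] = 0.0
    rhs = t_eff.sum(axis=1)
    try:
        omega = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError:
        omega = np.linalg.lstsq(m, rhs, rcond=None)[0]
    if np.any(omega < _OMEGA_FLOOR):
        logger.warning("sparcc: %d basis variances floored", int((omega < _OMEGA_FLOOR).sum()))
    return np.maximum(omega, _OMEGA_FLOOR)


def _rho_from(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _one_iteration(
    counts: np.ndarray,
    rng: np.random.Generator,
    exclusion_threshold: float,
    exclusion_rounds: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, set[tuple[int, int]]]:
    # Dirichlet(counts + 1) fraction draw via gamma sampling
    alpha = counts + 1.0
    gam = rng.standard_gamma(alpha)
    fracs = gam / gam.sum(axis=1, keepdims=True)
    logf = np.log(fracs)
    t = _logratio_variance(logf)
    excluded: set[tuple[int, int]] = set()
    omega = _basis_variances(t, excluded)
    rho = _rho_from(t, omega)
    for _ in range(exclusion_rounds):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        # a component involved in nearly all exclusions would degenerate;
        # stop excluding when the system loses rank
        omega = _basis_variances(t, excluded)
        rho = _rho_from(t, omega)
    return rho, t, omega, excluded


def sparcc(
    m: AbundanceMatrix,
    inner_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    seed: int | np.random.Generator = 0,
) -> SparccResult:
    """Estimate basis correlations from compositional counts.

    Requires at least 4 genomes (the basis-variance system is
    underdetermined below that).  The returned rho/t/omega are the
    elementwise medians across ``inner_iterations`` Dirichlet draws.
    """
    if m.n_genomes < 4:
        raise ValidationError("sparcc requires at least 4 genomes")
    if inner_iterations < 1:
        raise ValidationError("inner_iterations must be >= 1")
    counts = _as_counts(m)
    rng = np.random.default_rng(seed)
    rhos, ts, omegas = [], [], []
    excluded_last: set[tuple[int, int]] = set()
    for _ in range(inner_iterations):
        rho, t, omega, excluded = _one_iteration(
            counts, rng, exclusion_threshold, exclusion_rounds
        )
        rhos.append(rho)
        ts.append(t)
        omegas.append(omega)
        excluded_last = excluded
    rho_med = np.median(rhos, axis=0)
    rho_med = np.clip((rho_med + rho_med.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho_med, 1.0)
    return SparccResult(
        m.genome_ids,
        rho_med,
        np.median(ts, axis=0),
        np.median(omegas, axis=0),
        tuple(sorted(excluded_last)),
    )


def permutation_pvalues(
    m: AbundanceMatrix,
    observed: SparccResult,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    inner_iterations: int = 5,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
) -> np.ndarray:
    """Two-sided permutation p-values for SparCC correlations.

    Each permutation shuffles every genome's counts independently across
    samples (destroying cross-genome dependence, preserving marginals) and
    recomputes the correlation with ``inner_iterations`` Dirichlet draws.
    p_ij = (1 + #{|rho_null| >= |rho_obs|}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if tuple(observed.genome_ids) != tuple(m.genome_ids):
        raise ValidationError("observed result does not match the matrix")
    counts = _as_counts(m)
    n, d = counts.shape
    rng = np.random.default_rng(seed)
    obs_abs = np.abs(observed.rho)
    hits = np.zeros((d, d))
    for _ in range(n_permutations):
        shuffled = np.empty_like(counts)
        for j in range(d):
            shuffled[:, j] = counts[rng.permutation(n), j]
        null = sparcc(
            AbundanceMatrix(m.sample_ids, m.genome_ids, shuffled, "counts"),
            inner_iterations=inner_iterations,
            exclusion_threshold=exclusion_threshold,
            exclusion_rounds=exclusion_rounds,
            seed=rng,
        )
        hits += np.abs(null.rho) >= obs_abs - 1e-12
    p = (1.0 + hits) / (1.0 + n_permutations)
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 1.0)
    return p


def build_network(
    result: SparccResult,
    p: np.ndarray,
    edge_p: float = 0.001,
    guilds: dict[str, str] | None = None,
) -> EdgeList:
    """Retain genome pairs with p <= edge_p as signed edges.

    When a guild assignment is supplied, positive/negative counts within
    and between guilds are logged.
    """
    d = result.n
    if p.shape != (d, d):
        raise ValidationError("p matrix not aligned to correlations")
    edges = []
    for i in range(d):
        for j in range(i + 1, d):
            if p[i, j] <= edge_p:
                edges.append(
                    Edge(
                        result.genome_ids[i],
                        result.genome_ids[j],
                        float(result.rho[i, j]),
                        float(p[i, j]),
                    )
                )
    el = EdgeList(result.genome_ids, tuple(edges), edge_p)
    if guilds is not None:
        stats = edge_sign_summary(el, guilds)
        logger.info("edge sign summary: %s", stats)
    return el


def edge_sign_summary(e: EdgeList, guilds: dict[str, str]) -> dict[str, int]:
    """Count positive/negative edges within and between guilds."""
    out = {
        "within_positive": 0,
        "within_negative": 0,
        "between_positive": 0,
        "between_negative": 0,
    }
    for edge in e.edges:
        ga = guilds.get(edge.genome_a, "unassigned")
        gb = guilds.get(edge.genome_b, "unassigned")
        scope = "within" if ga == gb else "between"
        out[f"{scope}_{edge.sign}"] += 1
    return out


def connected_components(e: EdgeList, mode: str = "all_edges") -> list[set[str]]:
    """Union-find components over all edges or positive edges only."""
    if mode not in ("all_edges", "positive_only"):
        raise ValidationError(f"unknown mode {mode!r}")
    parent = {g: g for g in e.genome_ids}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for edge in e.edges:
        if mode == "positive_only" and edge.sign != "positive":
            continue
        ra, rb = find(edge.genome_a), find(edge.genome_b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for g in e.genome_ids:
        groups.setdefault(find(g), set()).add(g)
    return sorted(groups.values(), key=lambda s: (-len(s), sorted(s)))
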