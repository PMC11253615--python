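"""Hellinger transform, community distances, Simpson diversity, and PCoA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from guildscope.core_io import AbundanceMatrix, ValidationError, to_relative

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if np.max(np.abs(v - v.T), initial=0.0) > _SYM_TOL:
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > _SYM_TOL):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("distances must be >= 0")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def subset(self, ids) -> "DistanceMatrix":
        pos = {s: k for k, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)], self.metric_name)


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinates embedding."""

    ids: tuple[str, ...]
    coordinates: np.ndarray  # (n_samples, n_positive_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # over positive eigenvalues


def hellinger(m: AbundanceMatrix) -> AbundanceMatrix:
    """Square root of row-relative abundance.

    Output rows have squared entries summing to 1.  Counts are converted
    to relative abundance first.
    """
    if m.mode == "counts":
        m = to_relative(m)
    sums = m.values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(
            f"hellinger undefined for all-zero sample {m.sample_ids[zero[0]]!r}"
        )
    # rows no longer sum to 1 (their squares do), so the output does not
    # carry the "relative" row-sum invariant
    return AbundanceMatrix(
        m.sample_ids, m.genome_ids, np.sqrt(m.values / sums[:, None]), "counts"
    )


def bray_curtis(m: AbundanceMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = sum|a_i - b_i| / sum(a_i + b_i)."""
    if m.mode == "counts":
        m = to_relative(m)
    zero_rows = np.flatnonzero(m.values.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        raise ValidationError(
            "Bray-Curtis undefined between all-zero samples "
            f"{[m.sample_ids[i] for i in zero_rows]}"
        )
    d = squareform(pdist(m.values, metric="braycurtis"))
    return DistanceMatrix(m.sample_ids, d, "braycurtis")


def euclidean(values: np.ndarray, ids) -> DistanceMatrix:
    d = squareform(pdist(np.asarray(values, dtype=float), metric="euclidean"))
    return DistanceMatrix(tuple(ids), d, "euclidean")


def simpson_diversity(p, convention: str = "gini") -> float:
    """Simpson diversity of a nonnegative composition.

    Default convention is Gini-Simpson ``1 - sum q_i^2`` with ``q = p/sum p``
    (range ``[0, 1 - 1/k]``); ``convention="inverse"`` returns ``1/sum q^2``.
    An all-zero vector returns 0 by convention (empty guild in a sample).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("abundances must be >= 0")
    total = p.sum()
    if total == 0:
        return 0.0
    q = p / total
    ssq = float(np.sum(q * q))
    if convention == "gini":
        return 1.0 - ssq
    if convention == "inverse":
        return 1.0 / ssq
    raise ValidationError(f"unknown Simpson convention {convention!r}")


def pcoa(d: DistanceMatrix, correction: str | None = None) -> OrdinationResult:
    """Principal coordinates analysis (classical MDS).

    Gower-centers ``-d**2 / 2`` and eigendecomposes; coordinates use
    positive eigenvalues only, while negative eigenvalues are retained in
    the report.  Axis signs are fixed by making the largest-magnitude
    loading on each axis positive.  No eigenvalue correction by default.
    """
    n = d.n
    if n < 3:
        raise ValidationError("pcoa requires at least 3 samples")
    a = -0.5 * d.values**2
    if correction == "cailliez":
        a = _cailliez(d.values)
    elif correction not in (None, "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    centered = _gower_center(a)
    eigvals, eigvecs = np.linalg.eigh(centered)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # eigenvalues that are numerically zero count as neither pos nor neg
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return OrdinationResult(d.ids, coords, eigvals, prop)


def _gower_center(a: np.ndarray) -> np.ndarray:
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _cailliez(d: np.ndarray) -> np.ndarray:
    # smallest additive constant making the configuration Euclidean
    n = d.shape[0]
    g1 = _gower_center(-0.5 * d**2)
    g2 = _gower_center(-0.5 * d)
    z = np.zeros((n, n))
    block = np.block([[z, 2 * g1], [-np.eye(n), -4 * g2]])
    c = float(np.max(np.real(np.linalg.eigvals(block))))
    dc = d + c * (1 - np.eye(n))
    return -0.5 * dc**2
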