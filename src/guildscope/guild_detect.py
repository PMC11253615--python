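"""Guild detection from co-abundance correlations.

Complete-linkage hierarchical clustering on a dissimilarity derived from
either the signed WGCNA-style topological overlap of the correlation
matrix (default) or the correlation itself; the tree is cut into a fixed
number of guilds.  Labels can be anchored to clinical direction (eGFR)
so that guild1 is the protective guild.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from guildscope.core_io import AbundanceMatrix, ValidationError

logger = logging.getLogger("guildscope")

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GuildAssignment:
    """genome -> guild label partition with linkage-tree metadata."""

    genome_ids: tuple[str, ...]
    labels: tuple[str, ...]  # "guild1", "guild2", ..., "unassigned"
    linkage_tree: np.ndarray | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genome_ids) != len(self.labels):
            raise ValidationError("labels do not match genome ids")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.genome_ids, self.labels))

    def members(self, guild: str) -> list[str]:
        return [g for g, lab in zip(self.genome_ids, self.labels) if lab == guild]

    @property
    def guild_names(self) -> list[str]:
        seen = sorted({lab for lab in self.labels if lab != UNASSIGNED})
        return seen

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


def signed_tom(rho: np.ndarray, beta: int = 6) -> np.ndarray:
    """Signed adjacency + topological overlap similarity.

    a_ij = ((1 + rho_ij)/2)^beta (zero diagonal for connectivity);
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal.
    """
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValidationError("rho must be square")
    if np.any(np.abs(rho) > 1 + 1e-9):
        raise ValidationError("rho entries must lie in [-1, 1]")
    a = ((1.0 + np.clip(rho, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    min_k = np.minimum(k[:, None], k[None, :])
    tom = (shared + a) / (min_k + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_guilds(
    rho: np.ndarray,
    genome_ids,
    method: str = "tom_tree",
    n_guilds: int = 2,
    min_guild_size: int = 3,
    beta: int = 6,
    abundance: AbundanceMatrix | None = None,
) -> GuildAssignment:
    """Partition genomes into guilds by complete-linkage clustering.

    Distance is ``1 - TOM`` (``method="tom_tree"``, default) or
    ``1 - rho`` (``method="corr_tree"``).  Clusters smaller than
    ``min_guild_size`` are relabeled unassigned.  Guild numbering follows
    descending mean relative abundance when ``abundance`` is given,
    otherwise descending guild size (stable in genome order); use
    :func:`anchor_guild_labels` for clinically anchored numbering.
    """
    genome_ids = tuple(str(g) for g in genome_ids)
    rho = np.asarray(rho, dtype=float)
    d_genomes = len(genome_ids)
    if rho.shape != (d_genomes, d_genomes):
        raise ValidationError("rho not aligned to genome ids")
    if d_genomes < 2 * min_guild_size:
        raise ValidationError(
            f"need at least {2 * min_guild_size} genomes for {min_guild_size}-sized guilds"
        )
    if method == "tom_tree":
        dist = 1.0 - signed_tom(rho, beta=beta)
    elif method == "corr_tree":
        dist = 1.0 - np.clip(rho, -1.0, 1.0)
    else:
        raise ValidationError(f"unknown method {method!r}")
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    condensed = squareform(dist, checks=False)
    if np.ptp(condensed) == 0:
        raise ValidationError("degenerate distances: all pairs equally distant")
    tree = linkage(condensed, method="complete")
    clusters = fcluster(tree, t=n_guilds, criterion="maxclust")

    # drop undersized clusters
    sizes = {c: int(np.sum(clusters == c)) for c in np.unique(clusters)}
    kept = [c for c in sizes if sizes[c] >= min_guild_size]
    if not kept:
        raise ValidationError("no cluster reaches min_guild_size")

    # rank kept clusters: mean abundance if available, else size
    def rank_key(c: int) -> tuple:
        members = np.flatnonzero(clusters == c)
        if abundance is not None:
            pos = {g: k for k, g in enumerate(abundance.genome_ids)}
            cols = [pos[genome_ids[i]] for i in members if genome_ids[i] in pos]
            mean_ab = float(abundance.values[:, cols].mean()) if cols else 0.0
            return (-mean_ab, -sizes[c], c)
        return (-sizes[c], c)

    ordered = sorted(kept, key=rank_key)
    name_of = {c: f"guild{k + 1}" for k, c in enumerate(ordered)}
    labels = tuple(
        name_of.get(int(c), UNASSIGNED) for c in clusters
    )
    return GuildAssignment(
        genome_ids,
        labels,
        linkage_tree=tree,
        parameters={
            "method": method,
            "n_guilds": n_guilds,
            "min_guild_size": min_guild_size,
            "beta": beta,
        },
    )


def anchor_guild_labels(
    assignment: GuildAssignment,
    indices: dict[str, np.ndarray],
    egfr: np.ndarray,
) -> GuildAssignment:
    """Relabel guilds by clinical direction.

    The guild whose per-sample index correlates positively with eGFR
    becomes guild1 (protective); negative correlation becomes guild2
    (detrimental).  Ties in sign are broken by larger |correlation|.  If
    every correlation is zero/undefined the abundance-based labels are
    kept with a warning.
    """
    guilds = assignment.guild_names
    if len(guilds) < 2:
        raise ValidationError("anchoring requires at least 2 guilds")
    egfr = np.asarray(egfr, dtype=float)
    corr: dict[str, float] = {}
    for g in guilds:
        idx = np.asarray(indices[g], dtype=float)
        ok = np.isfinite(idx) & np.isfinite(egfr)
        if ok.sum() < 3 or np.ptp(egfr[ok]) == 0 or np.ptp(idx[ok]) == 0:
            corr[g] = 0.0
        else:
            corr[g] = float(spearmanr(idx[ok], egfr[ok]).statistic)
    if all(c == 0.0 for c in corr.values()):
        logger.warning("anchor_guild_labels: all correlations zero; keeping labels")
        return assignment
    # most-positive first, most-negative last; |corr| breaks sign ties
    ordered = sorted(guilds, key=lambda g: (-np.sign(corr[g]), -abs(corr[g])))
    rename = {old: f"guild{k + 1}" for k, old in enumerate(ordered)}
    labels = tuple(rename.get(lab, lab) for lab in assignment.labels)
    params = dict(assignment.parameters)
    params["anchored"] = {g: corr[g] for g in guilds}
    return GuildAssignment(assignment.genome_ids, labels, assignment.linkage_tree, params)
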