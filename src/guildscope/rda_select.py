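"""Constrained-ordination screening of genomes.

With group membership as the only constraint, the constrained axes of an
RDA on Hellinger-transformed abundance jointly span the column space of
the group design, so the fraction of a genome's variance explained by the
constrained axes equals its least-squares R-squared on the group
indicators.  Genomes at or above the selection threshold (default 10%)
form the signature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from guildscope.core_io import AbundanceMatrix, ValidationError
from guildscope.transforms_distance import hellinger

logger = logging.getLogger("guildscope")


@dataclass(frozen=True)
class SelectionResult:
    genome_id: str
    variance_explained: float
    selected: bool


def rda_variance_explained(
    m: AbundanceMatrix, group, apply_hellinger: bool = True
) -> pd.Series:
    """Per-genome fraction of variance explained by the group constraint.

    Columns are centered and projected onto the group indicator design;
    variance_explained(g) = ||fitted_g||^2 / ||centered_g||^2.  Constant
    genome columns get 0 with a warning.
    """
    group = np.asarray(group).astype(str)
    if group.shape[0] != m.n_samples:
        raise ValidationError("group labels not aligned to abundance matrix")
    levels, codes = np.unique(group, return_inverse=True)
    if levels.size < 2:
        raise ValidationError("group factor needs at least 2 levels")
    x = hellinger(m).values if apply_hellinger else m.values
    xc = x - x.mean(axis=0)
    # group-mean projection == hat matrix of the indicator design
    fitted = np.empty_like(xc)
    for k in range(levels.size):
        rows = codes == k
        fitted[rows] = xc[rows].mean(axis=0)
    ss_fit = np.sum(fitted**2, axis=0)
    ss_tot = np.sum(xc**2, axis=0)
    ve = np.zeros(m.n_genomes)
    nonconst = ss_tot > 0
    ve[nonconst] = ss_fit[nonconst] / ss_tot[nonconst]
    n_const = int((~nonconst).sum())
    if n_const:
        logger.warning(
            "rda_variance_explained: %d constant genome column(s) set to 0", n_const
        )
    return pd.Series(ve, index=list(m.genome_ids), name="variance_explained")


def select_signature(
    ve: pd.Series, threshold: float = 0.10
) -> list[SelectionResult]:
    """Threshold per-genome variance explained (inclusive, 'at least').

    Returns results sorted by variance_explained descending.
    """
    if not (0 < threshold < 1):
        raise ValidationError("threshold must lie in (0, 1)")
    ordered = ve.sort_values(ascending=False, kind="stable")
    return [
        SelectionResult(str(g), float(v), bool(v >= threshold))
        for g, v in ordered.items()
    ]


def selected_ids(results: list[SelectionResult]) -> list[str]:
    return [r.genome_id for r in results if r.selected]
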