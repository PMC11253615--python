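"""Per-sample guild index.

For a guild N and sample j the index is the guild's total relative
abundance times the Simpson diversity of its members within the sample:

    index_j = (sum_{i in N} A_ij) * (1 - sum_i q_i^2),  q_i = A_ij / total

A sample where the guild is absent scores 0, as does a one-member guild
(Gini-Simpson of a single taxon is 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from guildscope.core_io import AbundanceMatrix, ValidationError, to_relative
from guildscope.guild_detect import GuildAssignment
from guildscope.transforms_distance import simpson_diversity


def guild_index(
    m: AbundanceMatrix,
    assignment: GuildAssignment,
    convention: str = "gini",
) -> pd.DataFrame:
    """Guild indices for every guild in ``assignment``.

    Returns a DataFrame indexed by sample id with one column per guild
    (``guild1_index``, ``guild2_index``, ...).  Counts are converted to
    relative abundance first so the index is depth-comparable.
    """
    if m.mode == "counts":
        m = to_relative(m)
    guilds = assignment.guild_names
    if not guilds:
        raise ValidationError("assignment contains no guilds")
    present = set(m.genome_ids)
    pos = {g: k for k, g in enumerate(m.genome_ids)}
    out = {}
    for guild in guilds:
        members = assignment.members(guild)
        missing = [g for g in members if g not in present]
        if missing:
            raise ValidationError(
                f"{guild} members missing from abundance matrix: {missing}"
            )
        cols = [pos[g] for g in members]
        sub = m.values[:, cols]
        totals = sub.sum(axis=1)
        idx = np.array(
            [
                t * simpson_diversity(row, convention=convention) if t > 0 else 0.0
                for row, t in zip(sub, totals)
            ]
        )
        out[f"{guild}_index"] = idx
    return pd.DataFrame(out, index=list(m.sample_ids))


def guild_index_vectors(
    m: AbundanceMatrix, assignment: GuildAssignment, convention: str = "gini"
) -> dict[str, np.ndarray]:
    """Indices keyed by guild name (convenience for label anchoring)."""
    table = guild_index(m, assignment, convention=convention)
    return {
        guild: table[f"{guild}_index"].to_numpy()
        for guild in assignment.guild_names
    }
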