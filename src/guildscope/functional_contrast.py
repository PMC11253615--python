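"""Guild-level functional comparisons from per-genome annotations.

Carrier contrasts for gene families (Fisher's exact on the 2x2 guild x
carrier table), copy-number contrasts (Mann-Whitney), guild-unique module
detection from flat KO lists, and a KO-copy-number ordination of the
signature genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from guildscope.core_io import GenomeAnnotation, ValidationError
from guildscope.group_stats import fisher_exact_2x2, mann_whitney
from guildscope.guild_detect import GuildAssignment
from guildscope.permanova import PermanovaResult, permanova_single
from guildscope.transforms_distance import OrdinationResult, euclidean, pcoa


@dataclass(frozen=True)
class CarrierTable:
    gene: str
    guild_a: str
    guild_b: str
    carriers_a: int
    total_a: int
    carriers_b: int
    total_b: int

    def as_2x2(self) -> list[list[int]]:
        return [
            [self.carriers_a, self.total_a - self.carriers_a],
            [self.carriers_b, self.total_b - self.carriers_b],
        ]


def _guild_pair(assignment: GuildAssignment) -> tuple[str, str]:
    guilds = assignment.guild_names
    if len(guilds) < 2:
        raise ValidationError("need at least two guilds for a contrast")
    return guilds[0], guilds[1]


def _gene_column(ann: GenomeAnnotation, gene: str) -> pd.Series:
    if gene not in ann.gene_copies.columns:
        raise ValidationError(
            f"unknown gene {gene!r}; valid names: {sorted(ann.gene_copies.columns)}"
        )
    return ann.gene_copies[gene]


def carrier_contrast(
    ann: GenomeAnnotation, assignment: GuildAssignment, gene: str
) -> tuple[CarrierTable, tuple[float, float]]:
    """Fisher contrast of carrier counts (copy >= 1) between two guilds."""
    col = _gene_column(ann, gene)
    ga, gb = _guild_pair(assignment)
    members_a = assignment.members(ga)
    members_b = assignment.members(gb)
    carriers_a = int((col.reindex(members_a).fillna(0) >= 1).sum())
    carriers_b = int((col.reindex(members_b).fillna(0) >= 1).sum())
    table = CarrierTable(gene, ga, gb, carriers_a, len(members_a), carriers_b, len(members_b))
    fisher = fisher_exact_2x2(table.as_2x2())
    return table, fisher


def copy_number_contrast(
    ann: GenomeAnnotation, assignment: GuildAssignment, gene: str
) -> tuple[dict[str, np.ndarray], tuple[float, float]]:
    """Two-sided Mann-Whitney on per-genome copy numbers between guilds."""
    col = _gene_column(ann, gene)
    ga, gb = _guild_pair(assignment)
    copies = {
        ga: col.reindex(assignment.members(ga)).fillna(0).to_numpy(dtype=float),
        gb: col.reindex(assignment.members(gb)).fillna(0).to_numpy(dtype=float),
    }
    result = mann_whitney(copies[ga], copies[gb])
    return copies, result


def modules_present(
    ann: GenomeAnnotation,
    genomes: list[str],
    catalog: dict[str, set[str]],
    completeness: float = 1.0,
) -> set[str]:
    """Modules carried by at least one genome at the completeness level.

    A module counts as present in a genome when the genome carries at
    least ``completeness`` of the module's KO set (per-genome rule — KOs
    split across different genomes do not combine).
    """
    if not catalog:
        raise ValidationError("empty module catalog")
    ko = ann.ko_copies.reindex(genomes).fillna(0)
    present: set[str] = set()
    for module, kos in catalog.items():
        kos = set(kos)
        if not kos:
            raise ValidationError(f"module {module!r} has an empty KO set")
        have = [k for k in kos if k in ko.columns]
        if len(have) / len(kos) < completeness:
            continue
        carried = (ko[have] >= 1).sum(axis=1)
        if np.any(carried.to_numpy() >= completeness * len(kos)):
            present.add(module)
    return present


def unique_modules(
    ann: GenomeAnnotation,
    assignment: GuildAssignment,
    catalog: dict[str, set[str]],
    completeness: float = 1.0,
) -> dict[str, set[str]]:
    """Per-guild module sets and both guild-unique differences."""
    ga, gb = _guild_pair(assignment)
    mod_a = modules_present(ann, assignment.members(ga), catalog, completeness)
    mod_b = modules_present(ann, assignment.members(gb), catalog, completeness)
    return {
        ga: mod_a,
        gb: mod_b,
        f"unique_{ga}": mod_a - mod_b,
        f"unique_{gb}": mod_b - mod_a,
    }


def ko_ordination(
    ann: GenomeAnnotation,
    assignment: GuildAssignment,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[OrdinationResult, PermanovaResult]:
    """PCoA + PERMANOVA of guild genomes in Euclidean KO-copy space."""
    ga, gb = _guild_pair(assignment)
    genomes = assignment.members(ga) + assignment.members(gb)
    if len(genomes) < 3:
        raise ValidationError("ko_ordination requires at least 3 genomes")
    ko = ann.ko_copies.reindex(genomes).fillna(0)
    d = euclidean(ko.to_numpy(dtype=float), genomes)
    ordination = pcoa(d)
    labels = [ga] * len(assignment.members(ga)) + [gb] * len(assignment.members(gb))
    perm = permanova_single(
        d, labels, n_permutations=n_permutations, seed=seed, term="guild"
    )
    return ordination, perm


def arg_vf_summary(
    ann: GenomeAnnotation, assignment: GuildAssignment
) -> pd.DataFrame:
    """Per-guild tallies of ARG- and VF-carrying genomes and totals."""
    rows = []
    pos = {g: k for k, g in enumerate(ann.genome_ids)}
    for guild in assignment.guild_names:
        members = [g for g in assignment.members(guild) if g in pos]
        idx = [pos[g] for g in members]
        arg = ann.arg_count[idx]
        vf = ann.vf_count[idx]
        rows.append(
            {
                "guild": guild,
                "n_genomes": len(members),
                "arg_carriers": int((arg > 0).sum()),
                "arg_total": int(arg.sum()),
                "vf_carriers": int((vf > 0).sum()),
                "vf_carrier_fraction": float((vf > 0).mean()) if members else 0.0,
                "vf_total": int(vf.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("guild")
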