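"""Domain types, table readers/writers, configuration and run logging.

All tables are TSV with a mandatory header.  Abundance tables default to
samples-as-rows; the orientation can be flipped with ``samples_as_rows``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("guildscope")

GROUP_LEVELS = ("YHCG", "HCG", "EDG", "LDG")

_ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input table violates a contract."""


@dataclass(frozen=True)
class AbundanceMatrix:
    """Samples x genomes nonnegative abundance table.

    Parameters
    ----------
    sample_ids : tuple of str
        Ordered, unique sample identifiers (rows).
    genome_ids : tuple of str
        Ordered, unique genome identifiers (columns).
    values : ndarray of shape (n_samples, n_genomes)
        Nonnegative abundances; counts or relative abundance depending on
        ``mode``.
    mode : {"counts", "relative"}
    """

    sample_ids: tuple[str, ...]
    genome_ids: tuple[str, ...]
    values: np.ndarray
    mode: str = "counts"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "genome_ids", tuple(str(g) for g in self.genome_ids))
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown abundance mode {self.mode!r}")
        if values.ndim != 2:
            raise ValidationError("abundance values must be a 2-D array")
        if values.shape != (len(self.sample_ids), len(self.genome_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.genome_ids)} genomes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValidationError("duplicate genome ids")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance for sample {self.sample_ids[i]!r}, "
                f"genome {self.genome_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance {values[i, j]} for sample "
                f"{self.sample_ids[i]!r}, genome {self.genome_ids[j]!r}"
            )
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.flatnonzero(sums > 1 + _ROW_SUM_TOL)
            if bad.size:
                raise ValidationError(
                    f"relative-abundance row for sample {self.sample_ids[bad[0]]!r} "
                    f"sums to {sums[bad[0]]} > 1"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.genome_ids)
        )

    def subset_genomes(self, genome_ids: Iterable[str]) -> "AbundanceMatrix":
        """Restrict to the given genome columns, in the given order."""
        wanted = list(genome_ids)
        missing = [g for g in wanted if g not in set(self.genome_ids)]
        if missing:
            raise ValidationError(f"genomes not in matrix: {missing}")
        pos = {g: k for k, g in enumerate(self.genome_ids)}
        idx = [pos[g] for g in wanted]
        return AbundanceMatrix(
            self.sample_ids, tuple(wanted), self.values[:, idx], self.mode
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in set(self.sample_ids)]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in wanted]
        return AbundanceMatrix(
            tuple(wanted), self.genome_ids, self.values[idx, :], self.mode
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample group label, age, and clinical variables.

    ``clinical`` is a DataFrame indexed by sample id; missing values are
    permitted and propagate as pairwise-complete deletion downstream.
    """

    sample_ids: tuple[str, ...]
    group: tuple[str, ...]
    age: np.ndarray
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "group", tuple(str(g) for g in self.group))
        age = np.asarray(self.age, dtype=float)
        object.__setattr__(self, "age", age)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in metadata")
        n = len(self.sample_ids)
        if len(self.group) != n or age.shape != (n,):
            raise ValidationError("metadata fields have inconsistent lengths")
        with np.errstate(invalid="ignore"):
            if np.any(age[~np.isnan(age)] <= 0):
                raise ValidationError("age must be > 0 where present")
        clinical = self.clinical
        if not isinstance(clinical, pd.DataFrame):
            clinical = pd.DataFrame(clinical, index=list(self.sample_ids))
        clinical = clinical.reindex(list(self.sample_ids))
        object.__setattr__(self, "clinical", clinical)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_array(self) -> np.ndarray:
        return np.asarray(self.group, dtype=object)

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        wanted = list(sample_ids)
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise ValidationError(f"samples not in metadata: {missing}")
        idx = [pos[s] for s in wanted]
        return SampleMetadata(
            tuple(wanted),
            tuple(self.group[i] for i in idx),
            self.age[idx],
            self.clinical.iloc[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"group": list(self.group), "age": self.age}, index=list(self.sample_ids)
        )
        return pd.concat([df, self.clinical], axis=1)


@dataclass(frozen=True)
class GenomeAnnotation:
    """Per-genome gene copy numbers, ARG/VF tallies, and KO copy numbers.

    ``gene_copies`` and ``ko_copies`` are DataFrames indexed by genome id
    with nonnegative integer entries.
    """

    genome_ids: tuple[str, ...]
    gene_copies: pd.DataFrame
    arg_count: np.ndarray
    vf_count: np.ndarray
    ko_copies: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "genome_ids", tuple(str(g) for g in self.genome_ids))
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValidationError("duplicate genome ids in annotation")
        ids = list(self.genome_ids)
        gene = self.gene_copies.reindex(ids).fillna(0).astype(int)
        ko = self.ko_copies.reindex(ids).fillna(0).astype(int)
        arg = np.asarray(self.arg_count, dtype=int)
        vf = np.asarray(self.vf_count, dtype=int)
        for name, arr in (("gene_copies", gene.values), ("ko_copies", ko.values)):
            if np.any(arr < 0):
                raise ValidationError(f"negative value in {name}")
        if np.any(arg < 0) or np.any(vf < 0):
            raise ValidationError("ARG/VF counts must be >= 0")
        object.__setattr__(self, "gene_copies", gene)
        object.__setattr__(self, "ko_copies", ko)
        object.__setattr__(self, "arg_count", arg)
        object.__setattr__(self, "vf_count", vf)

    def subset(self, genome_ids: Iterable[str]) -> "GenomeAnnotation":
        wanted = list(genome_ids)
        pos = {g: k for k, g in enumerate(self.genome_ids)}
        missing = [g for g in wanted if g not in pos]
        if missing:
            raise ValidationError(f"genomes not in annotation: {missing}")
        idx = [pos[g] for g in wanted]
        return GenomeAnnotation(
            tuple(wanted),
            self.gene_copies.iloc[idx],
            self.arg_count[idx],
            self.vf_count[idx],
            self.ko_copies.iloc[idx],
        )


@dataclass
class RunConfig:
    """Thresholds, algorithm parameters and seeding for a full run."""

    seed: int = 0
    rda_min_variance: float = 0.10
    edge_p: float = 0.001
    n_permutations: int = 1000
    permanova_permutations: int = 999
    sparcc_inner_iterations: int = 20
    sparcc_exclusion_threshold: float = 0.1
    sparcc_exclusion_rounds: int = 10
    sparcc_null_inner_iterations: int = 5
    guild_method: str = "tom_tree"
    n_guilds: int = 2
    min_guild_size: int = 3
    tom_beta: int = 6
    simpson_convention: str = "gini"
    rf_n_trees: int = 500
    rf_max_features: str = "sqrt"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.rda_min_variance < 1):
            raise ValidationError("rda_min_variance must lie in (0,1)")
        if not (0 < self.edge_p < 1):
            raise ValidationError("edge_p must lie in (0,1)")
        if self.n_permutations < 1 or self.permanova_permutations < 1:
            raise ValidationError("permutation counts must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers / writers


def read_abundance(
    path: str | Path, mode: str = "counts", samples_as_rows: bool = True
) -> AbundanceMatrix:
    """Read a TSV abundance table into an :class:`AbundanceMatrix`.

    The file must carry a header row and an id column; with
    ``samples_as_rows`` (default) rows are samples and columns genomes.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not samples_as_rows:
        df = df.T
    _check_duplicates(df.index, "sample", path)
    _check_duplicates(df.columns, "genome", path)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative abundance {values[i, j]} for sample "
            f"{df.index[i]!r}, genome {df.columns[j]!r}"
        )
    return AbundanceMatrix(
        tuple(map(str, df.index)), tuple(map(str, df.columns)), values, mode
    )


def write_abundance(m: AbundanceMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV with columns ``group``, ``age``, clinicals."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_duplicates(df.index, "sample", path)
    for col in ("group", "age"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    clinical = df.drop(columns=["group", "age"])
    return SampleMetadata(
        tuple(map(str, df.index)),
        tuple(map(str, df["group"])),
        df["age"].to_numpy(dtype=float),
        clinical.astype(float),
    )


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(
    gene_path: str | Path, ko_path: str | Path | None = None
) -> GenomeAnnotation:
    """Read annotation tables.

    ``gene_path`` holds one row per genome with gene-family copy columns
    plus ``arg_count``/``vf_count``; ``ko_path`` (optional) holds KO copy
    numbers, one row per genome.
    """
    df = pd.read_csv(gene_path, sep="\t", index_col=0)
    _check_duplicates(df.index, "genome", gene_path)
    arg = df.pop("arg_count").to_numpy() if "arg_count" in df else np.zeros(len(df), int)
    vf = df.pop("vf_count").to_numpy() if "vf_count" in df else np.zeros(len(df), int)
    ko = (
        pd.read_csv(ko_path, sep="\t", index_col=0)
        if ko_path is not None
        else pd.DataFrame(index=df.index)
    )
    return GenomeAnnotation(tuple(map(str, df.index)), df, arg, vf, ko)


def write_annotation(
    ann: GenomeAnnotation, gene_path: str | Path, ko_path: str | Path | None = None
) -> None:
    genes = ann.gene_copies.copy()
    genes["arg_count"] = ann.arg_count
    genes["vf_count"] = ann.vf_count
    genes.to_csv(gene_path, sep="\t", index_label="genome_id")
    if ko_path is not None:
        ann.ko_copies.to_csv(ko_path, sep="\t", index_label="genome_id")


def _check_duplicates(index, kind: str, path) -> None:
    dup = pd.Index(index)[pd.Index(index).duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate {kind} id {dup[0]!r}")


# ---------------------------------------------------------------------------
# Basic transforms


def to_relative(m: AbundanceMatrix) -> AbundanceMatrix:
    """Close each row to relative abundance.

    Idempotent on relative input.  All-zero rows are rejected because the
    closure is undefined for them.
    """
    sums = m.values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(
            f"cannot convert to relative abundance: sample "
            f"{m.sample_ids[zero[0]]!r} has zero total abundance"
        )
    return AbundanceMatrix(
        m.sample_ids, m.genome_ids, m.values / sums[:, None], "relative"
    )


def align(
    m: AbundanceMatrix, meta: SampleMetadata
) -> tuple[AbundanceMatrix, SampleMetadata]:
    """Restrict matrix and metadata to their shared samples, same order.

    The intersection keeps the abundance-matrix row order.  Dropped ids
    are logged.
    """
    meta_ids = set(meta.sample_ids)
    shared = [s for s in m.sample_ids if s in meta_ids]
    if not shared:
        raise ValidationError("no shared samples between matrix and metadata")
    dropped_m = m.n_samples - len(shared)
    dropped_meta = meta.n_samples - len(shared)
    if dropped_m or dropped_meta:
        logger.info(
            "align: dropped %d matrix samples and %d metadata samples",
            dropped_m,
            dropped_meta,
        )
    return m.subset_samples(shared), meta.subset(shared)


# ---------------------------------------------------------------------------
# Run manifest / logging


def write_manifest(config: RunConfig, out_dir: str | Path, **extra) -> Path:
    """Write a JSON manifest (seed, thresholds, versions) next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def setup_logging(log_file: str | Path | None = None, level=logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
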