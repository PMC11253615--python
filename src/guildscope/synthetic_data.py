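"""Synthetic cohorts with planted two-guild structure.

A latent-factor log-normal model: each sample carries two jointly Gaussian
latent factors (g1, g2) with a negative target correlation; guild genomes
load on their guild's factor with Uniform(0.5, 1.5) loadings; background
genomes get independent log-normal noise.  Group severity shifts the
factor means monotonically (g1 down, g2 up across the four groups),
clinical variables are linear in the factors plus noise, and per-guild
gene-carrier rates generate the annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guildscope.core_io import (
    AbundanceMatrix,
    GenomeAnnotation,
    SampleMetadata,
    ValidationError,
    GROUP_LEVELS,
)

# carrier rates (guild1, guild2) for gene families; the butyrate terminal
# gene is strongly guild1-biased, tryptophanase occurs only in guild2
DEFAULT_CARRIER_RATES: dict[str, tuple[float, float]] = {
    "but": (14 / 34, 2 / 20),
    "buk": (0.05, 0.05),
    "atoA": (0.0, 0.05),
    "atoD": (0.0, 0.05),
    "4Hbt": (0.20, 0.05),
    "fdtl": (0.40, 0.20),
    "pct": (23 / 34, 4 / 20),
    "pst": (0.30, 0.10),
    "tnaA": (0.0, 2 / 20),
}

# clinical variable -> (coef_g1, coef_g2, intercept, noise_sd); signs follow
# the protective-guild1 / detrimental-guild2 pattern
DEFAULT_CLINICAL_COUPLING: dict[str, tuple[float, float, float, float]] = {
    "eGFR": (12.0, -12.0, 80.0, 10.0),
    "UACR": (-300.0, 300.0, 800.0, 300.0),
    "ALB": (4.0, -4.0, 40.0, 4.0),
    "HbA1c": (-0.5, 0.5, 7.0, 0.8),
    "LDH": (-20.0, 20.0, 200.0, 30.0),
}


@dataclass
class SimulationSpec:
    """Parameters of the planted-structure generator."""

    group_sizes: tuple[int, int, int, int] = (45, 46, 57, 59)
    group_names: tuple[str, ...] = GROUP_LEVELS
    n_guild1: int = 34
    n_guild2: int = 20
    n_background: int = 200
    severity_effect: float = 1.2
    between_guild_corr: float = -0.6
    noise_sd: float = 0.6
    background_sd: float = 1.6
    depth: int = 50_000
    mode: str = "relative"
    dirichlet_overdispersion: float | None = None
    clinical_coupling: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_COUPLING)
    )
    carrier_rates: dict = field(default_factory=lambda: dict(DEFAULT_CARRIER_RATES))
    n_ko: int = 120
    ko_guild_unique: int = 20

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes):
            raise ValidationError("group sizes must be positive")
        if len(self.group_sizes) != len(self.group_names):
            raise ValidationError("group sizes and names differ in length")
        if not (-1.0 < self.between_guild_corr < 0.0) and self.between_guild_corr != 0.0:
            raise ValidationError("between_guild_corr must lie in (-1, 0] ")
        for gene, (p1, p2) in self.carrier_rates.items():
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise ValidationError(f"carrier rate for {gene!r} outside [0,1]")
        if self.mode not in ("relative", "counts"):
            raise ValidationError("mode must be 'relative' or 'counts'")


@dataclass(frozen=True)
class GroundTruth:
    roles: dict[str, str]  # genome -> guild1 | guild2 | background
    latent: pd.DataFrame  # per-sample g1, g2
    signal_genomes: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = set(self.roles.values())
        if not labels <= {"guild1", "guild2", "background"}:
            raise ValidationError(f"unexpected roles {labels}")


def _latent_factors(spec: SimulationSpec, rng: np.random.Generator):
    cov = np.array([[1.0, spec.between_guild_corr], [spec.between_guild_corr, 1.0]])
    eigvals = np.linalg.eigvalsh(cov)
    if np.any(eigvals <= 0):
        raise ValidationError("implied latent covariance is not positive definite")
    chol = np.linalg.cholesky(cov)
    n = sum(spec.group_sizes)
    raw = rng.standard_normal((n, 2)) @ chol.T
    # strictly monotone severity shifts: g1 decreasing, g2 increasing
    severity = np.repeat(np.arange(len(spec.group_sizes)), spec.group_sizes)
    raw[:, 0] -= spec.severity_effect * severity
    raw[:, 1] += spec.severity_effect * severity
    groups = np.repeat(np.asarray(spec.group_names, dtype=object), spec.group_sizes)
    return raw, groups


def simulate_community(
    spec: SimulationSpec, seed: int
) -> tuple[AbundanceMatrix, SampleMetadata, GenomeAnnotation, GroundTruth]:
    """Draw one synthetic cohort with planted two-guild structure."""
    rng = np.random.default_rng(seed)
    latent, groups = _latent_factors(spec, rng)
    n = latent.shape[0]

    g1_ids = [f"G1_{k:03d}" for k in range(spec.n_guild1)]
    g2_ids = [f"G2_{k:03d}" for k in range(spec.n_guild2)]
    bg_ids = [f"BG_{k:04d}" for k in range(spec.n_background)]
    genome_ids = g1_ids + g2_ids + bg_ids

    load1 = rng.uniform(0.5, 1.5, spec.n_guild1)
    load2 = rng.uniform(0.5, 1.5, spec.n_guild2)
    base1 = rng.normal(0.0, 0.5, spec.n_guild1)
    base2 = rng.normal(0.0, 0.5, spec.n_guild2)
    base_bg = rng.normal(0.0, 1.0, spec.n_background)

    log_ab = np.empty((n, len(genome_ids)))
    log_ab[:, : spec.n_guild1] = (
        base1 + latent[:, [0]] * load1 + rng.normal(0, spec.noise_sd, (n, spec.n_guild1))
    )
    s2 = slice(spec.n_guild1, spec.n_guild1 + spec.n_guild2)
    log_ab[:, s2] = (
        base2 + latent[:, [1]] * load2 + rng.normal(0, spec.noise_sd, (n, spec.n_guild2))
    )
    log_ab[:, spec.n_guild1 + spec.n_guild2 :] = base_bg + rng.normal(
        0, spec.background_sd, (n, spec.n_background)
    )
    raw = np.exp(log_ab)
    rel = raw / raw.sum(axis=1, keepdims=True)

    if spec.mode == "counts":
        if spec.dirichlet_overdispersion:
            conc = spec.dirichlet_overdispersion
            rel_draw = np.vstack([rng.dirichlet(conc * row) for row in rel])
        else:
            rel_draw = rel
        values = np.vstack(
            [rng.multinomial(spec.depth, row) for row in rel_draw]
        ).astype(float)
        matrix = AbundanceMatrix(
            tuple(f"S{k:03d}" for k in range(n)), tuple(genome_ids), values, "counts"
        )
    else:
        matrix = AbundanceMatrix(
            tuple(f"S{k:03d}" for k in range(n)), tuple(genome_ids), rel, "relative"
        )

    meta = _metadata(spec, rng, matrix.sample_ids, groups, latent)
    ann = _annotations(spec, rng, g1_ids, g2_ids, bg_ids)
    truth = GroundTruth(
        roles={
            **{g: "guild1" for g in g1_ids},
            **{g: "guild2" for g in g2_ids},
            **{g: "background" for g in bg_ids},
        },
        latent=pd.DataFrame(latent, index=list(matrix.sample_ids), columns=["g1", "g2"]),
        signal_genomes=tuple(g1_ids + g2_ids),
    )
    return matrix, meta, ann, truth


def _metadata(spec, rng, sample_ids, groups, latent) -> SampleMetadata:
    n = len(sample_ids)
    # the first group is the younger healthy control; others share an
    # older age distribution
    age = np.where(
        groups == spec.group_names[0],
        rng.normal(35.0, 5.0, n),
        rng.normal(55.0, 8.0, n),
    )
    age = np.clip(age, 20.0, 80.0)
    clinical = {}
    for name, (c1, c2, intercept, sd) in spec.clinical_coupling.items():
        clinical[name] = (
            intercept + c1 * latent[:, 0] + c2 * latent[:, 1] + rng.normal(0, sd, n)
        )
    return SampleMetadata(
        tuple(sample_ids),
        tuple(groups),
        age,
        pd.DataFrame(clinical, index=list(sample_ids)),
    )


def _annotations(spec, rng, g1_ids, g2_ids, bg_ids) -> GenomeAnnotation:
    genome_ids = g1_ids + g2_ids + bg_ids
    gene = {}
    for name, (p1, p2) in spec.carrier_rates.items():
        carrier = np.concatenate(
            [
                rng.random(len(g1_ids)) < p1,
                rng.random(len(g2_ids)) < p2,
                rng.random(len(bg_ids)) < (p1 + p2) / 2,
            ]
        )
        copies = np.where(carrier, 1 + rng.poisson(0.5, len(genome_ids)), 0)
        gene[name] = copies
    gene_df = pd.DataFrame(gene, index=genome_ids)

    # ARG/VF: guild2-biased burdens
    arg = np.concatenate(
        [
            rng.binomial(1, 0.05, len(g1_ids)),
            rng.binomial(2, 0.3, len(g2_ids)),
            rng.binomial(1, 0.1, len(bg_ids)),
        ]
    )
    vf = np.concatenate(
        [
            rng.poisson(2.5, len(g1_ids)),
            rng.poisson(16.0, len(g2_ids)),
            rng.poisson(4.0, len(bg_ids)),
        ]
    )

    # KO profiles: shared pool plus guild-unique KO blocks
    n_shared = spec.n_ko
    n_unique = spec.ko_guild_unique
    cols = (
        [f"K{k:05d}" for k in range(n_shared)]
        + [f"KU1_{k:03d}" for k in range(n_unique)]
        + [f"KU2_{k:03d}" for k in range(n_unique)]
    )
    ko = np.zeros((len(genome_ids), len(cols)), dtype=int)
    n1, n2 = len(g1_ids), len(g2_ids)
    ko[:, :n_shared] = rng.binomial(2, 0.3, (len(genome_ids), n_shared))
    ko[:n1, n_shared : n_shared + n_unique] = rng.binomial(1, 0.6, (n1, n_unique))
    ko[n1 : n1 + n2, n_shared + n_unique :] = rng.binomial(1, 0.6, (n2, n_unique))
    ko_df = pd.DataFrame(ko, index=genome_ids, columns=cols)

    return GenomeAnnotation(tuple(genome_ids), gene_df, arg, vf, ko_df)


def simulate_null(
    spec: SimulationSpec, seed: int
) -> tuple[AbundanceMatrix, SampleMetadata]:
    """Same machinery with zero severity effect and clinical coupling.

    Group labels carry no signal; useful for type-I-error calibration.
    """
    import dataclasses

    null_spec = dataclasses.replace(
        spec,
        severity_effect=0.0,
        clinical_coupling={
            name: (0.0, 0.0, c[2], c[3]) for name, c in spec.clinical_coupling.items()
        },
    )
    matrix, meta, _, _ = simulate_community(null_spec, seed)
    return matrix, meta
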