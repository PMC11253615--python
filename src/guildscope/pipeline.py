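"""End-to-end orchestration of the guild analysis.

Stage order: distances + PERMANOVA on the full matrix; RDA screening of
genomes; SparCC correlation and network on the signature set; guild
detection and clinical anchoring; guild indices and group statistics;
control-vs-case classification; functional contrasts when annotations are
available.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from guildscope import core_io
from guildscope.classify_eval import EvalCurves, pr_auc, rf_loocv_scores, transfer_classifier
from guildscope.coabundance import (
    EdgeList,
    build_network,
    edge_sign_summary,
    permutation_pvalues,
    sparcc,
)
from guildscope.core_io import (
    AbundanceMatrix,
    GenomeAnnotation,
    RunConfig,
    SampleMetadata,
    ValidationError,
    align,
    to_relative,
)
from guildscope.functional_contrast import arg_vf_summary, carrier_contrast
from guildscope.group_stats import bh_adjust, kruskal_dunn_cld, partial_spearman
from guildscope.guild_detect import GuildAssignment, anchor_guild_labels, detect_guilds
from guildscope.guild_index import guild_index, guild_index_vectors
from guildscope.permanova import pairwise_permanova, permanova_marginal, permanova_single
from guildscope.rda_select import rda_variance_explained, select_signature, selected_ids
from guildscope.transforms_distance import bray_curtis

logger = logging.getLogger("guildscope")

CONTROL_GROUPS = ("YHCG", "HCG")
CASE_GROUPS = ("EDG", "LDG")


@dataclass
class PipelineReport:
    seed: int
    config: dict
    stages: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    # in-memory artifacts for downstream use
    signature: list[str] = field(default_factory=list)
    assignment: GuildAssignment | None = None
    indices: pd.DataFrame | None = None
    edges: EdgeList | None = None
    loocv: EvalCurves | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "stages": self.stages,
                "warnings": self.warnings,
                "summary": self.summary,
            },
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def binarize_groups(groups) -> np.ndarray:
    """{YHCG, HCG} -> 0 (control), {EDG, LDG} -> 1 (case)."""
    groups = np.asarray(groups).astype(str)
    known = set(CONTROL_GROUPS) | set(CASE_GROUPS)
    unknown = set(groups) - known
    if unknown:
        raise ValidationError(f"unknown group labels {sorted(unknown)}")
    return np.isin(groups, CASE_GROUPS).astype(int)


def run_pipeline(
    matrix: AbundanceMatrix,
    meta: SampleMetadata,
    config: RunConfig,
    annotation: GenomeAnnotation | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run every stage on aligned inputs; returns a PipelineReport.

    Outputs (when ``out_dir`` given) are written stage by stage so a
    failure leaves completed stages on disk.
    """
    t0 = time.time()
    report = PipelineReport(seed=config.seed, config=config.to_dict())
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name: str) -> None:
        logger.info("stage %-18s t=%.1fs", name, time.time() - t0)
        report.stages.append(name)

    matrix, meta = align(matrix, meta)
    rel = to_relative(matrix) if matrix.mode == "counts" else matrix
    groups = meta.group_array()

    # -- community structure: Bray-Curtis + PERMANOVA -----------------------
    stage("permanova")
    bc = bray_curtis(rel)
    single = permanova_single(
        bc, groups, n_permutations=config.permanova_permutations, seed=config.seed,
        term="group",
    )
    marginal = permanova_marginal(
        bc,
        {"age": meta.age, "group": groups},
        n_permutations=config.permanova_permutations,
        seed=config.seed + 1,
    )
    pairwise = pairwise_permanova(
        bc, groups, n_permutations=config.permanova_permutations, seed=config.seed + 2
    )
    report.summary["permanova"] = {
        "single_group": single.to_dict(),
        "marginal": {k: v.to_dict() for k, v in marginal.items()},
        "pairwise": [r.to_dict() for r in pairwise],
    }

    # -- RDA screening ------------------------------------------------------
    stage("rda_select")
    ve = rda_variance_explained(rel, groups)
    selection = select_signature(ve, threshold=config.rda_min_variance)
    signature = selected_ids(selection)
    if not signature:
        raise ValidationError(
            "no signature genomes: every genome fell below the RDA "
            f"variance-explained threshold {config.rda_min_variance}"
        )
    report.signature = signature
    report.summary["n_signature"] = len(signature)
    if out is not None:
        pd.DataFrame(
            [(r.genome_id, r.variance_explained, r.selected) for r in selection],
            columns=["genome_id", "variance_explained", "selected"],
        ).to_csv(out / "rda_selection.tsv", sep="\t", index=False)

    # -- co-abundance network on the signature ------------------------------
    stage("coabundance")
    sig_matrix = matrix.subset_genomes(signature)
    sp = sparcc(
        sig_matrix,
        inner_iterations=config.sparcc_inner_iterations,
        exclusion_threshold=config.sparcc_exclusion_threshold,
        exclusion_rounds=config.sparcc_exclusion_rounds,
        seed=config.seed + 10,
    )
    pvals = permutation_pvalues(
        sig_matrix,
        sp,
        n_permutations=config.n_permutations,
        seed=config.seed + 11,
        inner_iterations=config.sparcc_null_inner_iterations,
        exclusion_threshold=config.sparcc_exclusion_threshold,
        exclusion_rounds=config.sparcc_exclusion_rounds,
    )
    edges = build_network(sp, pvals, edge_p=config.edge_p)
    report.edges = edges
    report.summary["n_edges"] = len(edges)

    # -- guild detection ----------------------------------------------------
    stage("guild_detect")
    rel_sig = rel.subset_genomes(signature)
    assignment = detect_guilds(
        sp.rho,
        signature,
        method=config.guild_method,
        n_guilds=config.n_guilds,
        min_guild_size=config.min_guild_size,
        beta=config.tom_beta,
        abundance=rel_sig,
    )
    indices0 = guild_index_vectors(rel_sig, assignment, convention=config.simpson_convention)
    if "eGFR" in meta.clinical.columns and len(assignment.guild_names) >= 2:
        assignment = anchor_guild_labels(
            assignment, indices0, meta.clinical["eGFR"].to_numpy()
        )
    report.assignment = assignment
    report.summary["guild_sizes"] = assignment.sizes()
    report.summary["edge_signs"] = edge_sign_summary(edges, assignment.as_dict())
    if out is not None:
        pd.DataFrame(
            {"genome_id": assignment.genome_ids, "guild": assignment.labels}
        ).to_csv(out / "guilds.tsv", sep="\t", index=False)
        edges.to_frame().to_csv(out / "edges.tsv", sep="\t", index=False)

    # -- guild indices + group stats ----------------------------------------
    stage("guild_index")
    indices = guild_index(rel_sig, assignment, convention=config.simpson_convention)
    report.indices = indices
    kw = {
        col: kruskal_dunn_cld(indices[col].to_numpy(), groups, variable=col)
        for col in indices.columns
    }
    report.summary["index_kw"] = {
        col: {"H": r.h_statistic, "p": r.p, "letters": r.letters}
        for col, r in kw.items()
    }

    stage("clinical_correlation")
    clin_results = {}
    raw_ps, keys = [], []
    for col in indices.columns:
        for var in meta.clinical.columns:
            try:
                res = partial_spearman(
                    indices[col].to_numpy(), meta.clinical[var].to_numpy(), meta.age
                )
            except ValidationError:
                continue
            clin_results[(col, var)] = res
            raw_ps.append(res.p)
            keys.append((col, var))
    adj = bh_adjust(raw_ps) if raw_ps else []
    report.summary["clinical_partial_spearman"] = {
        f"{col}~{var}": {
            "rho": clin_results[(col, var)].rho,
            "p": clin_results[(col, var)].p,
            "p_adjusted": float(pa),
        }
        for (col, var), pa in zip(keys, adj)
    }

    # -- classification -----------------------------------------------------
    stage("classify")
    y = binarize_groups(groups)
    scores = rf_loocv_scores(
        rel_sig,
        y,
        params={"n_trees": config.rf_n_trees, "max_features": config.rf_max_features},
        seed=config.seed + 20,
    )
    curves = pr_auc(scores, y)
    report.loocv = curves
    report.summary["loocv"] = {
        "auroc": curves.auroc,
        "auprc": curves.auprc,
        "pr_baseline": curves.pr_baseline,
    }
    if out is not None:
        pd.DataFrame(
            {"sample_id": rel_sig.sample_ids, "score": scores, "label": y}
        ).to_csv(out / "loocv_scores.tsv", sep="\t", index=False)

    # -- functional contrasts -----------------------------------------------
    if annotation is not None and len(assignment.guild_names) >= 2:
        stage("functional_contrast")
        contrasts = {}
        for gene in annotation.gene_copies.columns:
            table, (odds, p) = carrier_contrast(annotation, assignment, gene)
            contrasts[gene] = {
                "carriers": [table.carriers_a, table.total_a, table.carriers_b, table.total_b],
                "odds_ratio": odds,
                "p": p,
            }
        report.summary["carrier_contrasts"] = contrasts
        report.summary["arg_vf"] = arg_vf_summary(annotation, assignment).to_dict()

    if out is not None:
        indices.to_csv(out / "guild_indices.tsv", sep="\t", index_label="sample_id")
        (out / "report.json").write_text(report.to_json())
        core_io.write_manifest(config, out, stages=report.stages)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return report


def run_validation(
    report: PipelineReport,
    train: tuple[AbundanceMatrix, np.ndarray],
    external: tuple[AbundanceMatrix, np.ndarray],
    config: RunConfig,
) -> EvalCurves:
    """Score an external cohort with a forest trained on the study data.

    The external matrix is restricted/zero-filled to the signature genome
    columns inside :func:`transfer_classifier`.
    """
    m_train, y_train = train
    m_ext, y_ext = external
    y_ext = np.asarray(y_ext)
    if np.unique(y_ext).size < 2:
        raise ValidationError("external labels must contain both classes")
    sig = report.signature
    if not sig:
        raise ValidationError("report carries no signature genomes")
    train_sig = m_train.subset_genomes(sig)
    return transfer_classifier(
        (train_sig, y_train),
        (m_ext, y_ext),
        params={"n_trees": config.rf_n_trees, "max_features": config.rf_max_features},
        seed=config.seed + 30,
    )
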