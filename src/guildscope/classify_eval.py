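"""Random-forest classification and from-first-principles ROC/PR curves.

The forest itself is delegated to scikit-learn; scoring, leave-one-out
cross-validation, AUROC (trapezoid over the threshold sweep) and AUPRC
(step-wise average precision, interpolation-free) are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from guildscope.core_io import AbundanceMatrix, ValidationError

logger = logging.getLogger("guildscope")


@dataclass(frozen=True)
class EvalCurves:
    scores: np.ndarray
    labels: np.ndarray  # 0/1
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auroc: float
    pr_recall: np.ndarray | None = None
    pr_precision: np.ndarray | None = None
    auprc: float | None = None
    pr_baseline: float | None = None


def _validate_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    uniq = np.unique(y)
    if uniq.size > 2:
        raise ValidationError("labels must contain at most two classes")
    try:
        if set(uniq.tolist()) <= {0, 1}:
            return y.astype(int)
    except TypeError:
        pass
    if uniq.size != 2:
        raise ValidationError("labels must contain exactly two classes")
    # map the two classes to 0/1; the larger (sorted-last) label is positive
    return (y == uniq[-1]).astype(int)


def _forest(params: dict | None, seed: int) -> RandomForestClassifier:
    params = dict(params or {})
    return RandomForestClassifier(
        n_estimators=params.get("n_trees", 500),
        max_features=params.get("max_features", "sqrt"),
        random_state=seed,
        n_jobs=1,
    )


def rf_loocv_scores(
    m: AbundanceMatrix, labels, params: dict | None = None, seed: int = 0
) -> np.ndarray:
    """Leave-one-out random-forest positive-class probabilities.

    Each held-out sample is scored by a forest trained on the others; the
    per-fold seed derives from ``seed`` so the whole procedure is
    deterministic.
    """
    y = _validate_binary(labels)
    if np.unique(y).size < 2:
        raise ValidationError("labels must contain both classes")
    x = m.values
    n = x.shape[0]
    if n < 10:
        raise ValidationError("leave-one-out needs at least 10 samples")
    if y.shape[0] != n:
        raise ValidationError("labels not aligned to matrix")
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = _forest(params, seed + i)
        clf.fit(x[mask], y[mask])
        proba = clf.predict_proba(x[i : i + 1])[0]
        scores[i] = proba[list(clf.classes_).index(1)] if 1 in clf.classes_ else 0.0
        mask[i] = True
    return scores


def roc_auc(scores, labels) -> EvalCurves:
    """ROC curve and AUROC by threshold sweep with simultaneous tie steps."""
    y = _validate_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes required for ROC")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied score block
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return EvalCurves(s, y, fpr, tpr, auroc)


def pr_auc(scores, labels) -> EvalCurves:
    """Precision-recall curve and step-wise AUPRC (average precision).

    AUPRC = sum over positives, in decreasing-score order, of
    precision-at-that-point weighted by the recall increment; tied scores
    are processed as one block.  The baseline equals the positive
    fraction.
    """
    y = np.asarray(_validate_binary(labels))
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValidationError("at least one positive required for PR")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    preds = np.arange(1, y.size + 1)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    precision = tps[distinct] / preds[distinct]
    recall = tps[distinct] / n_pos
    auprc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    roc = roc_auc(s, y) if np.unique(y).size == 2 else None
    baseline = n_pos / y.size
    return EvalCurves(
        s,
        y,
        roc.roc_fpr if roc else np.array([]),
        roc.roc_tpr if roc else np.array([]),
        roc.auroc if roc else float("nan"),
        pr_recall=np.r_[0.0, recall],
        pr_precision=np.r_[precision[:1], precision],
        auprc=auprc,
        pr_baseline=float(baseline),
    )


def transfer_classifier(
    train: tuple[AbundanceMatrix, np.ndarray],
    test: tuple[AbundanceMatrix, np.ndarray],
    params: dict | None = None,
    seed: int = 0,
) -> EvalCurves:
    """Train one forest on the full training set; evaluate on the test set.

    Test columns are aligned to the training genome set; genomes missing
    from the test matrix are zero-filled with a warning.
    """
    m_train, y_train = train
    m_test, y_test = test
    y_train = _validate_binary(y_train)
    y_test = _validate_binary(y_test)
    if np.unique(y_train).size < 2:
        raise ValidationError("training labels must contain both classes")
    shared = [g for g in m_train.genome_ids if g in set(m_test.genome_ids)]
    if not shared:
        raise ValidationError("no overlapping genomes between train and test")
    missing = [g for g in m_train.genome_ids if g not in set(m_test.genome_ids)]
    test_cols = np.zeros((m_test.n_samples, m_train.n_genomes))
    pos = {g: k for k, g in enumerate(m_test.genome_ids)}
    for k, g in enumerate(m_train.genome_ids):
        if g in pos:
            test_cols[:, k] = m_test.values[:, pos[g]]
    if missing:
        logger.warning(
            "transfer_classifier: %d training genomes absent from test set, "
            "zero-filled",
            len(missing),
        )
    clf = _forest(params, seed)
    clf.fit(m_train.values, y_train)
    proba = clf.predict_proba(test_cols)
    col = list(clf.classes_).index(1)
    scores = proba[:, col]
    curves = pr_auc(scores, y_test)
    return curves
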