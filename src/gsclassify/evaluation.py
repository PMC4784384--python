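"""Target-class classification metrics and the cross-validation harness.

ROC curves sweep every distinct score as a threshold (predicted positive iff
score strictly greater than the threshold) with +/- infinity sentinels; the
trapezoidal area equals the Mann-Whitney statistic with ties counted half.
Precision-recall curves are summarized by average precision with tied scores
processed as a block. The harness runs a classifier over the partitions of a
PINDX-style PartitionSet and aggregates mean and sample standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .discretize import ClassLabeling, one_hot
from .io import Dataset, PartitionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ScoredBinary:
    """Target-class scores with one-vs-rest boolean labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be aligned 1-D vectors")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())


@dataclass(frozen=True)
class Curve:
    kind: Literal["roc", "pr"]
    points: list[tuple[float, float]]
    area: float


@dataclass
class CVResult:
    per_partition: list[float]
    metric_name: str
    target_class: str
    classifier: str
    skipped: int = 0
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.per_partition, dtype=float)
        self.mean = float(vals.mean()) if vals.size else float("nan")
        self.sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")

    def format_mean_sd(self, digits: int = 3) -> str:
        return f"{self.mean:.{digits}f}({self.sd:.{digits}f})"


# ---------------------------------------------------------------------------
# Scalar metrics


def confusion_at_threshold(sb: ScoredBinary, tau: float) -> ConfusionMatrix:
    """Counts with the rule: predicted positive iff score > tau (strict)."""
    pred = sb.scores > tau
    return ConfusionMatrix(
        tp=int((pred & sb.labels).sum()),
        fp=int((pred & ~sb.labels).sum()),
        fn=int((~pred & sb.labels).sum()),
        tn=int((~pred & ~sb.labels).sum()),
    )


def recall(cm: ConfusionMatrix) -> float:
    """tp / (tp + fn); undefined (error) when there are no positives."""
    if cm.tp + cm.fn == 0:
        raise ValueError("recall undefined: no observed positives")
    return cm.tp / (cm.tp + cm.fn)


def fpr(cm: ConfusionMatrix) -> float:
    """fp / (fp + tn); undefined (error) when there are no negatives."""
    if cm.fp + cm.tn == 0:
        raise ValueError("false positive rate undefined: no observed negatives")
    return cm.fp / (cm.fp + cm.tn)


def precision(cm: ConfusionMatrix) -> float:
    """tp / (tp + fp), with the empty-prediction convention P = 1."""
    if cm.tp + cm.fp == 0:
        return 1.0
    return cm.tp / (cm.tp + cm.fp)


def _block_counts(sb: ScoredBinary) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct scores (descending) with cumulative tp/fp after each block."""
    order = np.argsort(-sb.scores, kind="mergesort")
    s = sb.scores[order]
    y = sb.labels[order]
    # last index of each distinct-score block
    last = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tps = np.cumsum(y)[last].astype(float)
    fps = np.cumsum(~y)[last].astype(float)
    return s[last], tps, fps


def roc_auc(
    scores: np.ndarray | ScoredBinary, labels: np.ndarray | None = None
) -> Curve:
    """ROC curve over the full threshold sweep and its trapezoidal area.

    Equals the Mann-Whitney statistic with tied score pairs counted 1/2.
    """
    sb = scores if isinstance(scores, ScoredBinary) else ScoredBinary(scores, labels)
    if sb.n_pos == 0 or sb.n_neg == 0:
        raise ValueError(
            f"degenerate fold: {sb.n_pos} positives / {sb.n_neg} negatives; "
            "ROC is undefined"
        )
    _, tps, fps = _block_counts(sb)
    tpr = np.r_[0.0, tps / sb.n_pos]
    fpr_ = np.r_[0.0, fps / sb.n_neg]
    area = float(np.trapezoid(tpr, fpr_))
    return Curve("roc", list(zip(fpr_.tolist(), tpr.tolist())), area)


def pr_auc(
    scores: np.ndarray | ScoredBinary, labels: np.ndarray | None = None
) -> Curve:
    """Precision-recall curve and average precision (step integration).

    AP = sum over descending-score blocks of precision(after block) *
    delta-recall(block); tied scores are handled as one block.
    """
    sb = scores if isinstance(scores, ScoredBinary) else ScoredBinary(scores, labels)
    if sb.n_pos == 0:
        raise ValueError("average precision undefined: no observed positives")
    _, tps, fps = _block_counts(sb)
    rec = tps / sb.n_pos
    prec = tps / (tps + fps)
    d_rec = np.diff(np.r_[0.0, rec])
    area = float(np.sum(prec * d_rec))
    points = [(0.0, 1.0)] + list(zip(rec.tolist(), prec.tolist()))
    return Curve("pr", points, area)


def one_vs_rest(
    P: np.ndarray, lab: ClassLabeling, target_class: int | None = None
) -> ScoredBinary:
    """Reduce an S x n score matrix to target-class scores and binary labels."""
    P = np.asarray(P, dtype=float)
    k = lab.target_class if target_class is None else target_class
    if not 0 <= k < P.shape[0]:
        raise ValueError(f"target class {k} out of range for {P.shape[0]} classes")
    return ScoredBinary(P[k], lab.labels == k)


# ---------------------------------------------------------------------------
# Cross-validation harness


def _pnn_partition_scorer(params: dict) -> Callable:
    from .pnn import pnn_fit, pnn_predict_proba, select_bandwidth

    grid = params.get("grid")
    posterior = params.get("posterior", "softmax")
    val_frac = params.get("val_frac", 0.12)

    def score(X_tr, C_tr, lab_tr, X_te, seed):
        h, _ = select_bandwidth(
            X_tr, C_tr, lab_tr, grid=grid, val_frac=val_frac,
            seed=seed, posterior=posterior,
        )
        model = pnn_fit(X_tr, C_tr, h)
        return pnn_predict_proba(model, X_te, posterior=posterior)

    return score


def _mlp_partition_scorer(params: dict) -> Callable:
    from .mlp import mlp_ensemble_predict

    def score(X_tr, C_tr, lab_tr, X_te, seed):
        return mlp_ensemble_predict(
            X_tr, C_tr, lab_tr, X_te,
            M_grid=params.get("M_grid", (1, 2, 3, 4)),
            replicates=params.get("replicates", 10),
            seed=seed,
            val_frac=params.get("val_frac", 0.12),
            max_epochs=params.get("max_epochs", 1000),
            patience=params.get("patience", 6),
            aggregate="scores",
        )

    return score


def run_cv(
    ds: Dataset,
    lab: ClassLabeling,
    pset: PartitionSet,
    classifier: Literal["pnn", "mlp"] = "pnn",
    params: dict | None = None,
    metrics: Sequence[str] = ("auc", "aucpr"),
    seed: int | None = 0,
) -> dict[str, CVResult]:
    """Train and score over every partition; aggregate target-class metrics.

    Per partition the classifier is tuned (inner validation, target-class AUC)
    and fit on code-1 individuals, then scores code-2 individuals. Partitions
    whose test fold misses the target class or contains a single class are
    skipped with a warning. Returns one CVResult per requested metric, all
    computed from the same fitted models.
    """
    if pset.n != ds.n or lab.n != ds.n:
        raise ValueError("partition set / labeling inconsistent with dataset size")
    params = dict(params or {})
    scorer = {"pnn": _pnn_partition_scorer, "mlp": _mlp_partition_scorer}[classifier](params)
    metric_fns = {"auc": roc_auc, "aucpr": pr_auc}
    for m in metrics:
        if m not in metric_fns:
            raise ValueError(f"unknown metric {m!r}")

    X = ds.markers.values.astype(float)
    C_full = one_hot(lab).C
    rng = np.random.default_rng(seed)
    per_metric: dict[str, list[float]] = {m: [] for m in metrics}
    skipped = 0
    for r in range(pset.R):
        tr, te = pset.train_test_indices(r)
        part_seed = int(rng.integers(0, 2**32))
        test_labels = lab.labels[te]
        if np.unique(test_labels).size < 2 or lab.target_class not in test_labels:
            logger.warning("partition %d has a degenerate test fold; skipped", r)
            skipped += 1
            continue
        lab_tr = ClassLabeling(
            scheme=lab.scheme,
            class_names=lab.class_names,
            labels=lab.labels[tr],
            counts=[int((lab.labels[tr] == k).sum()) for k in range(lab.n_classes)],
            target_class=lab.target_class,
            cut_values=lab.cut_values,
        )
        P = scorer(X[tr], C_full[:, tr], lab_tr, X[te], part_seed)
        sb = ScoredBinary(P[lab.target_class], test_labels == lab.target_class)
        for m in metrics:
            per_metric[m].append(metric_fns[m](sb).area)

    return {
        m: CVResult(
            per_partition=per_metric[m],
            metric_name=m,
            target_class=lab.target_name,
            classifier=classifier,
            skipped=skipped,
        )
        for m in metrics
    }
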