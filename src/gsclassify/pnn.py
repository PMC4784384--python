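"""Probabilistic neural network: a Gaussian-kernel Parzen/Bayes classifier.

The pattern layer places one Gaussian radial basis function at every training
input (center). For a query x and center c the activation is

    u = b * ||x - c||,   z = exp(-u^2),   b = sqrt(-ln 0.5) / h,

so z = 0.5 exactly when the query sits at distance h from the center. The
summation layer adds the kernel values of each class (weights taken directly
from the one-hot target matrix) and the output layer turns the class sums into
posterior probabilities. Fitting is a single pass: the model simply stores the
training inputs; only the bandwidth h is a free parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .discretize import ClassLabeling, TargetMatrix, inner_split, one_hot

Posterior = Literal["softmax", "sum_normalized"]


@dataclass(frozen=True)
class PNNModel:
    centers: np.ndarray  # M x p training inputs
    W: np.ndarray  # S x M class-indicator weights
    h: float
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        W = np.asarray(self.W)
        if centers.ndim != 2:
            raise ValueError("centers must be 2-D")
        if self.h <= 0:
            raise ValueError(f"bandwidth h must be positive, got {self.h}")
        if W.shape[1] != centers.shape[0]:
            raise ValueError("W columns must match number of centers")
        if not (W.sum(axis=0) == 1).all():
            raise ValueError("each center must belong to exactly one class")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "W", W.astype(float))

    @property
    def b(self) -> float:
        """Kernel weight: b * h = sqrt(ln 2)."""
        return math.sqrt(-math.log(0.5)) / self.h

    @property
    def M(self) -> int:
        return self.centers.shape[0]

    @property
    def S(self) -> int:
        return self.W.shape[0]

    @property
    def p(self) -> int:
        return self.centers.shape[1]


def pnn_fit(
    X_train: np.ndarray,
    C_train: TargetMatrix | np.ndarray,
    h: float,
    class_names: Sequence[str] | None = None,
) -> PNNModel:
    """Store training inputs as centers and the one-hot targets as weights."""
    X = np.asarray(X_train, dtype=float)
    C = C_train.C if isinstance(C_train, TargetMatrix) else np.asarray(C_train)
    if h <= 0:
        raise ValueError(f"bandwidth h must be positive, got {h}")
    if C.shape[1] != X.shape[0]:
        raise ValueError("C_train columns must align with X_train rows")
    if (C.sum(axis=1) == 0).any():
        missing = int(np.flatnonzero(C.sum(axis=1) == 0)[0])
        raise ValueError(f"class {missing} absent from training targets")
    return PNNModel(X, C, float(h), list(class_names) if class_names else None)


def pnn_activations(
    model: PNNModel,
    X: np.ndarray,
    block_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pattern- and summation-layer values for query rows X.

    Returns (U, Z, V): U[m, i] = b * ||x_i - c_m||, Z = exp(-U^2), V = W @ Z.
    Queries may be processed in blocks of ``block_size`` columns; the result
    is independent of the blocking.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.p:
        raise ValueError(f"query has {X.shape[1]} markers, model expects {model.p}")
    n = X.shape[0]
    U = np.empty((model.M, n))
    if block_size is None or block_size >= n:
        U[:] = model.b * cdist(model.centers, X)
    else:
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            U[:, start:stop] = model.b * cdist(model.centers, X[start:stop])
    Z = np.exp(-(U**2))
    V = model.W @ Z
    return U, Z, V


def pnn_predict_proba(
    model: PNNModel,
    X: np.ndarray,
    posterior: Posterior = "softmax",
    block_size: int | None = None,
) -> np.ndarray:
    """S x n posterior matrix: softmax over class sums (default) or plain
    sum-normalization v_k / sum_j v_j (uniform where all sums vanish)."""
    _, _, V = pnn_activations(model, X, block_size=block_size)
    if posterior == "softmax":
        V = V - V.max(axis=0, keepdims=True)
        E = np.exp(V)
        return E / E.sum(axis=0, keepdims=True)
    if posterior == "sum_normalized":
        total = V.sum(axis=0, keepdims=True)
        P = np.full_like(V, 1.0 / model.S)
        ok = total[0] > 0
        P[:, ok] = V[:, ok] / total[:, ok]
        return P
    raise ValueError(f"unknown posterior rule {posterior!r}")


def pnn_predict_class(
    model: PNNModel, X: np.ndarray, posterior: Posterior = "softmax"
) -> np.ndarray:
    """Argmax class per query; ties broken toward the lowest class index."""
    P = pnn_predict_proba(model, X, posterior=posterior)
    return P.argmax(axis=0)


def median_pairwise_distance(X: np.ndarray, max_rows: int = 600, seed: int = 0) -> float:
    """Median Euclidean distance between distinct rows (subsampled if large)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_rows, replace=False)]
    D = cdist(X, X)
    vals = D[np.triu_indices_from(D, k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("all training rows identical; cannot scale bandwidth grid")
    return float(np.median(vals))


def default_bandwidth_grid(X_train: np.ndarray, num: int = 20) -> np.ndarray:
    """Log-spaced grid spanning [0.01, 10] x median pairwise training distance."""
    scale = median_pairwise_distance(X_train)
    return scale * np.logspace(np.log10(0.01), np.log10(10.0), num)


def select_bandwidth(
    X_train: np.ndarray,
    C_train: TargetMatrix | np.ndarray,
    lab: ClassLabeling,
    grid: Sequence[float] | None = None,
    val_frac: float = 0.12,
    n_splits: int = 1,
    seed: int | None = 0,
    posterior: Posterior = "softmax",
) -> tuple[float, list[tuple[float, float]]]:
    """Choose the bandwidth maximizing target-class validation ROC-AUC.

    For each h in the grid the model is fit on stratified inner-training
    fold(s) and scored on the held-out fold(s); the h with the best mean
    validation AUC wins (ties -> smallest h). ``lab`` must be the labeling of
    the *training* rows, i.e. lab.n == X_train.shape[0].
    """
    from .evaluation import roc_auc  # local import to avoid a cycle

    X = np.asarray(X_train, dtype=float)
    C = C_train.C if isinstance(C_train, TargetMatrix) else np.asarray(C_train)
    if lab.n != X.shape[0]:
        raise ValueError("labeling must cover exactly the training rows")
    if grid is None:
        grid = default_bandwidth_grid(X)
    grid = [float(h) for h in grid]
    if not grid or any(h <= 0 for h in grid):
        raise ValueError("bandwidth grid must be non-empty and positive")

    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_splits):
        tr, va = inner_split(np.arange(X.shape[0]), lab, val_frac=val_frac, seed=rng)
        if np.unique(lab.labels[va]).size < 2 or lab.target_class not in lab.labels[va]:
            warnings.warn("degenerate validation fold skipped in bandwidth search", stacklevel=2)
            continue
        folds.append((tr, va))
    if not folds:
        raise ValueError("all validation folds degenerate; cannot select bandwidth")

    table: list[tuple[float, float]] = []
    for h in grid:
        aucs = []
        for tr, va in folds:
            model = pnn_fit(X[tr], C[:, tr], h)
            P = pnn_predict_proba(model, X[va], posterior=posterior)
            scores = P[lab.target_class]
            labels = lab.labels[va] == lab.target_class
            aucs.append(roc_auc(scores, labels).area)
        table.append((h, float(np.mean(aucs))))

    best_auc = max(a for _, a in table)
    h_star = min(h for h, a in table if a == best_auc)
    return h_star, table


# ---------------------------------------------------------------------------
# Persistence


def save_pnn(model: PNNModel, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "centers.csv", model.centers, delimiter=",")
    np.savetxt(out_dir / "weights.csv", model.W, delimiter=",")
    meta = {
        "h": float(model.h),
        "b": float(model.b),
        "M": model.M,
        "S": model.S,
        "p": model.p,
        "class_names": model.class_names,
    }
    with open(out_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return out_dir


def load_pnn(in_dir: str | Path) -> PNNModel:
    in_dir = Path(in_dir)
    centers = np.loadtxt(in_dir / "centers.csv", delimiter=",", ndmin=2)
    W = np.loadtxt(in_dir / "weights.csv", delimiter=",", ndmin=2)
    with open(in_dir / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    names = meta.get("class_names")
    return PNNModel(centers, W, float(meta["h"]), list(names) if names else None)
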