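"""Feed-forward multilayer perceptron classifier.

One hidden layer and an output layer, both with the hyperbolic tangent
sigmoid (tansig) transfer. Raw outputs in (-1, 1) are affinely mapped to
[0, 1] scores compared against 0/1 one-hot targets under a mean-squared-error
objective. Training is full-batch scaled conjugate gradient (Moller 1993)
with early stopping on a held-out validation split: the weights at the
minimum validation error are the ones returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .discretize import ClassLabeling, TargetMatrix, inner_split


def tansig(u):
    """Hyperbolic tangent sigmoid 2 / (1 + exp(-2u)) - 1 == tanh(u)."""
    return np.tanh(u)


@dataclass
class MLPModel:
    W_in: np.ndarray  # M x p
    b_in: np.ndarray  # M
    W_out: np.ndarray  # S x M
    b_out: np.ndarray  # S

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.b_in = np.asarray(self.b_in, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        M, p = self.W_in.shape
        S = self.W_out.shape[0]
        if self.b_in.shape != (M,) or self.W_out.shape != (S, M) or self.b_out.shape != (S,):
            raise ValueError("inconsistent weight shapes")
        for arr in (self.W_in, self.b_in, self.W_out, self.b_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weights")

    @property
    def M(self) -> int:
        return self.W_in.shape[0]

    @property
    def p(self) -> int:
        return self.W_in.shape[1]

    @property
    def S(self) -> int:
        return self.W_out.shape[0]


@dataclass
class TrainingTrace:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stop_iteration: int = 0
    best_iteration: int = 0


def init_model(p: int, M: int, S: int, rng: np.random.Generator) -> MLPModel:
    """Symmetric uniform init scaled by fan-in (Nguyen-Widrow-like)."""
    if M < 1:
        raise ValueError("hidden size M must be >= 1")
    a_in = 0.7 / np.sqrt(p)
    a_out = 0.7 / np.sqrt(M)
    return MLPModel(
        W_in=rng.uniform(-a_in, a_in, size=(M, p)),
        b_in=rng.uniform(-a_in, a_in, size=M),
        W_out=rng.uniform(-a_out, a_out, size=(S, M)),
        b_out=rng.uniform(-a_out, a_out, size=S),
    )


def mlp_forward(model: MLPModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden features Z (M x n) and [0,1] scores C_hat (S x n).

    Z = tansig(W_in x + b_in); raw outputs o = tansig(W_out z + b_out);
    C_hat = (o + 1) / 2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.p:
        raise ValueError(f"input has {X.shape[1]} features, model expects {model.p}")
    Z = tansig(model.W_in @ X.T + model.b_in[:, None])
    O = tansig(model.W_out @ Z + model.b_out[:, None])
    return Z, (O + 1.0) / 2.0


def mse_objective(C_hat: np.ndarray, C: TargetMatrix | np.ndarray) -> float:
    """Mean over all S*n entries of (C_hat - C)^2."""
    Ct = C.C if isinstance(C, TargetMatrix) else np.asarray(C, dtype=float)
    C_hat = np.asarray(C_hat, dtype=float)
    if C_hat.shape != Ct.shape:
        raise ValueError(f"shape mismatch {C_hat.shape} vs {Ct.shape}")
    return float(np.mean((C_hat - Ct) ** 2))


# ---------------------------------------------------------------------------
# Flattened-parameter loss/gradient (for SCG and gradient checking)


def _pack(model: MLPModel) -> np.ndarray:
    return np.concatenate(
        [model.W_in.ravel(), model.b_in, model.W_out.ravel(), model.b_out]
    )


def _unpack(w: np.ndarray, p: int, M: int, S: int) -> MLPModel:
    i = 0
    W_in = w[i : i + M * p].reshape(M, p); i += M * p
    b_in = w[i : i + M]; i += M
    W_out = w[i : i + S * M].reshape(S, M); i += S * M
    b_out = w[i : i + S]
    return MLPModel(W_in, b_in, W_out, b_out)


def loss_and_grad(
    w: np.ndarray, X: np.ndarray, C: np.ndarray, p: int, M: int, S: int
) -> tuple[float, np.ndarray]:
    """MSE loss and its backpropagated gradient for flattened parameters w."""
    model = _unpack(w, p, M, S)
    n = X.shape[0]
    A = model.W_in @ X.T + model.b_in[:, None]
    Z = np.tanh(A)
    B = model.W_out @ Z + model.b_out[:, None]
    O = np.tanh(B)
    C_hat = (O + 1.0) / 2.0
    diff = C_hat - C
    loss = float(np.mean(diff**2))

    # dL/dB = (2/(S n)) * diff * (1/2) * (1 - O^2)
    dB = diff * (1.0 - O**2) / (S * n)
    gW_out = dB @ Z.T
    gb_out = dB.sum(axis=1)
    dZ = model.W_out.T @ dB
    dA = dZ * (1.0 - Z**2)
    gW_in = dA @ X
    gb_in = dA.sum(axis=1)
    grad = np.concatenate([gW_in.ravel(), gb_in, gW_out.ravel(), gb_out])
    return loss, grad


def early_stopping_schedule(
    val_series: Sequence[float], patience: int
) -> tuple[int, int]:
    """(stop_iteration, best_iteration), both 1-based, for a validation trace.

    Stops once the count of consecutive epochs without improvement over the
    running best exceeds ``patience`` (or at the end of the series).
    """
    best = np.inf
    best_it = 0
    bad = 0
    stop_it = len(val_series)
    for i, v in enumerate(val_series, start=1):
        if v < best:
            best, best_it, bad = v, i, 0
        else:
            bad += 1
            if bad > patience:
                stop_it = i
                break
    return stop_it, best_it


def train_scg(
    model: MLPModel,
    X_train: np.ndarray,
    C_train: TargetMatrix | np.ndarray,
    X_val: np.ndarray,
    C_val: TargetMatrix | np.ndarray,
    max_epochs: int = 1000,
    patience: int = 6,
) -> tuple[MLPModel, TrainingTrace]:
    """Scaled-conjugate-gradient training with validation early stopping.

    Returns the weights observed at the minimum validation MSE together with
    the per-epoch trace. One epoch is one SCG iteration on the full batch.
    """
    Ct = C_train.C if isinstance(C_train, TargetMatrix) else np.asarray(C_train, dtype=float)
    Cv = C_val.C if isinstance(C_val, TargetMatrix) else np.asarray(C_val, dtype=float)
    Ct = Ct.astype(float)
    Cv = Cv.astype(float)
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    if X_val.shape[0] == 0:
        raise ValueError("validation set is empty")
    p, M, S = model.p, model.M, model.S

    def f(wv: np.ndarray) -> tuple[float, np.ndarray]:
        return loss_and_grad(wv, X_train, Ct, p, M, S)

    def val_mse(wv: np.ndarray) -> float:
        _, C_hat = mlp_forward(_unpack(wv, p, M, S), X_val)
        return float(np.mean((C_hat - Cv) ** 2))

    w = _pack(model)
    N = w.size
    sigma0 = 5e-5
    lam = 5e-7
    lam_bar = 0.0
    loss, grad = f(w)
    r = -grad
    d = r.copy()
    success = True
    delta = 0.0

    trace = TrainingTrace()
    best_val = np.inf
    best_w = w.copy()
    best_it = 0
    bad = 0

    for k in range(1, max_epochs + 1):
        if success:
            norm_d2 = float(d @ d)
            if norm_d2 == 0.0:
                break  # gradient vanished: converged
            sigma = sigma0 / np.sqrt(norm_d2)
            _, grad_sigma = f(w + sigma * d)
            s = (grad_sigma - grad) / sigma
            delta = float(d @ s)
        else:
            norm_d2 = float(d @ d)

        delta += (lam - lam_bar) * norm_d2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / norm_d2)
            delta = -delta + lam * norm_d2
            lam = lam_bar
        mu = float(d @ r)
        alpha = mu / delta
        loss_new, grad_new = f(w + alpha * d)
        if not np.isfinite(loss_new):
            raise FloatingPointError("non-finite training loss; aborting")
        Delta = 2.0 * delta * (loss - loss_new) / (mu**2)

        if Delta >= 0:  # successful step
            w = w + alpha * d
            loss = loss_new
            r_new = -grad_new
            lam_bar = 0.0
            success = True
            if k % N == 0:
                d = r_new.copy()  # restart
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                d = r_new + beta * d
            r = r_new
            grad = -r
            if Delta >= 0.75:
                lam *= 0.25
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam += delta * (1.0 - Delta) / norm_d2
        if lam > 1e100:
            break  # step size collapsed

        v = val_mse(w)
        trace.train_mse.append(loss)
        trace.val_mse.append(v)
        if v < best_val:
            best_val, best_w, best_it, bad = v, w.copy(), k, 0
        else:
            bad += 1
            if bad > patience:
                break

    trace.stop_iteration = len(trace.val_mse)
    trace.best_iteration = best_it
    return _unpack(best_w, p, M, S), trace


def select_hidden_size(
    X_train: np.ndarray,
    C_train: np.ndarray,
    lab: ClassLabeling,
    M_grid: Sequence[int],
    rng: np.random.Generator,
    val_frac: float = 0.12,
    max_epochs: int = 1000,
    patience: int = 6,
) -> tuple[MLPModel, int, float]:
    """Train one net per hidden size on a fresh stratified inner split; keep the
    one with the best target-class validation AUC (ties -> smallest M)."""
    from .evaluation import roc_auc

    tr, va = inner_split(np.arange(X_train.shape[0]), lab, val_frac=val_frac, seed=rng)
    if np.unique(lab.labels[va]).size < 2:
        raise ValueError("degenerate validation fold: a single class present")
    best: tuple[float, int, MLPModel] | None = None
    for M in sorted(M_grid):
        net = init_model(X_train.shape[1], M, C_train.shape[0], rng)
        net, _ = train_scg(
            net, X_train[tr], C_train[:, tr], X_train[va], C_train[:, va],
            max_epochs=max_epochs, patience=patience,
        )
        _, scores = mlp_forward(net, X_train[va])
        auc = roc_auc(scores[lab.target_class], lab.labels[va] == lab.target_class).area
        if best is None or auc > best[0]:
            best = (auc, M, net)
    assert best is not None
    return best[2], best[1], best[0]


def mlp_ensemble_predict(
    X_train: np.ndarray,
    C_train: TargetMatrix | np.ndarray,
    lab: ClassLabeling,
    X_test: np.ndarray,
    M_grid: Sequence[int] = (1, 2, 3, 4),
    replicates: int = 10,
    seed: int | None = 0,
    val_frac: float = 0.12,
    max_epochs: int = 1000,
    patience: int = 6,
    aggregate: Literal["scores", "per_replicate"] = "scores",
) -> np.ndarray:
    """Replicate-ensembled test scores.

    Each replicate draws a fresh stratified inner split and fresh weight
    initialization, selects the hidden size by target-class validation AUC,
    trains with early stopping, and scores the test rows. With
    ``aggregate='scores'`` the mean S x n score matrix is returned; with
    ``'per_replicate'`` the stacked (replicates, S, n) array.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    C = C_train.C if isinstance(C_train, TargetMatrix) else np.asarray(C_train)
    C = C.astype(float)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if lab.n != X_train.shape[0]:
        raise ValueError("labeling must cover exactly the training rows")

    rng = np.random.default_rng(seed)
    all_scores = np.empty((replicates, C.shape[0], X_test.shape[0]))
    for rep in range(replicates):
        try:
            net, _, _ = select_hidden_size(
                X_train, C, lab, M_grid, rng,
                val_frac=val_frac, max_epochs=max_epochs, patience=patience,
            )
        except ValueError as exc:
            warnings.warn(f"replicate {rep} failed ({exc}); reusing a fresh split", stacklevel=2)
            net, _, _ = select_hidden_size(
                X_train, C, lab, M_grid, rng,
                val_frac=val_frac, max_epochs=max_epochs, patience=patience,
            )
        _, scores = mlp_forward(net, X_test)
        all_scores[rep] = scores
    if aggregate == "per_replicate":
        return all_scores
    return all_scores.mean(axis=0)


# ---------------------------------------------------------------------------
# Persistence


def save_mlp(model: MLPModel, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "w_in.csv", model.W_in, delimiter=",")
    np.savetxt(out_dir / "b_in.csv", model.b_in, delimiter=",")
    np.savetxt(out_dir / "w_out.csv", model.W_out, delimiter=",")
    np.savetxt(out_dir / "b_out.csv", model.b_out, delimiter=",")
    meta = {"M": model.M, "S": model.S, "p": model.p, "transfer": ["tansig", "tansig"]}
    with open(out_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return out_dir


def load_mlp(in_dir: str | Path) -> MLPModel:
    in_dir = Path(in_dir)
    with open(in_dir / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    M, S, p = int(meta["M"]), int(meta["S"]), int(meta["p"])
    return MLPModel(
        np.loadtxt(in_dir / "w_in.csv", delimiter=",").reshape(M, p),
        np.loadtxt(in_dir / "b_in.csv", delimiter=",").reshape(M),
        np.loadtxt(in_dir / "w_out.csv", delimiter=",").reshape(S, M),
        np.loadtxt(in_dir / "b_out.csv", delimiter=",").reshape(S),
    )
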