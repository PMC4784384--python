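"""Percentile-based discretization of continuous traits and stratified splits.

Class boundaries use the nearest-rank quantile: the cut at fraction p is the
k-th smallest value with k = round(p * n), rounding half away from zero.
Individuals whose value equals a cut go to the lower side. With all-distinct
trait values this yields a lower class of exactly round(p_low * n) members and
an upper class of n - round(p_high * n) members.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .io import PartitionSet, PhenotypeVector

Tail = Literal["upper", "lower"]


def _round_half_up(x: float) -> int:
    """round() with halves away from zero (not banker's rounding)."""
    return int(math.floor(x + 0.5))


def nearest_rank_quantile(y: np.ndarray, p: float) -> float:
    """The k-th smallest value of y, k = round(p * n) half away from zero."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile fraction must be in (0, 1), got {p}")
    ys = np.sort(np.asarray(y, dtype=float))
    k = _round_half_up(p * ys.size)
    k = min(max(k, 1), ys.size)
    return float(ys[k - 1])


@dataclass(frozen=True)
class ClassLabeling:
    """Per-individual ordered class assignment derived from trait percentiles."""

    scheme: dict
    class_names: list[str]
    labels: np.ndarray
    counts: list[int]
    target_class: int
    cut_values: list[float]
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if sum(self.counts) != labels.size:
            raise ValueError("class counts do not sum to n")
        if not 0 <= self.target_class < len(self.class_names):
            raise ValueError("target_class out of range")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def target_name(self) -> str:
        return self.class_names[self.target_class]


@dataclass(frozen=True)
class TargetMatrix:
    """S x n one-hot class-indicator matrix (columns sum to one)."""

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C)
        if C.ndim != 2:
            raise ValueError("C must be 2-D")
        if not np.isin(C, (0, 1)).all():
            raise ValueError("C entries must be 0 or 1")
        if not (C.sum(axis=0) == 1).all():
            raise ValueError("every column of C must sum to exactly 1")
        object.__setattr__(self, "C", C.astype(np.int64))

    @property
    def S(self) -> int:
        return self.C.shape[0]

    @property
    def n(self) -> int:
        return self.C.shape[1]


def assign_three_classes(
    phenotype: PhenotypeVector | np.ndarray,
    p_low: float,
    p_high: float,
    target: Literal["lower", "middle", "upper"] = "upper",
) -> ClassLabeling:
    """Split a trait into lower / middle / upper classes at empirical quantiles.

    lower:  y <= q(p_low)
    middle: q(p_low) < y <= q(p_high)
    upper:  y > q(p_high)
    """
    if isinstance(phenotype, PhenotypeVector):
        y, ids = phenotype.y, list(phenotype.individual_ids)
    else:
        y, ids = np.asarray(phenotype, dtype=float), None
    if not (0.0 < p_low < p_high < 1.0):
        raise ValueError(f"need 0 < p_low < p_high < 1, got ({p_low}, {p_high})")
    if y.size < 3:
        raise ValueError("need at least 3 individuals for three classes")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant; classes would be degenerate")

    q_low = nearest_rank_quantile(y, p_low)
    q_high = nearest_rank_quantile(y, p_high)
    labels = np.where(y <= q_low, 0, np.where(y <= q_high, 1, 2)).astype(np.int64)
    counts = [int((labels == k).sum()) for k in range(3)]
    for k, c in enumerate(counts):
        if c == 0:
            warnings.warn(f"class {('lower', 'middle', 'upper')[k]!r} is empty", stacklevel=2)
    names = ["lower", "middle", "upper"]
    return ClassLabeling(
        scheme={"kind": "three_class", "p_low": p_low, "p_high": p_high},
        class_names=names,
        labels=labels,
        counts=counts,
        target_class=names.index(target),
        cut_values=[q_low, q_high],
        individual_ids=ids,
    )


def collapse_to_two_classes(lab: ClassLabeling, tail: Tail) -> ClassLabeling:
    """Collapse a three-class labeling into {tail} vs the union of the rest.

    The tail class is preserved exactly; the complement merges the other two
    classes. The tail becomes class 1 (and the target).
    """
    if lab.n_classes != 3:
        raise ValueError("collapse_to_two_classes requires a three-class labeling")
    tail_idx = {"lower": 0, "upper": 2}.get(tail)
    if tail_idx is None:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    labels = (lab.labels == tail_idx).astype(np.int64)
    counts = [int((labels == 0).sum()), int((labels == 1).sum())]
    p = lab.scheme.get("p_low" if tail == "lower" else "p_high")
    return ClassLabeling(
        scheme={"kind": "two_class", "tail": tail, "p": p},
        class_names=["other", tail],
        labels=labels,
        counts=counts,
        target_class=1,
        cut_values=[lab.cut_values[tail_idx // 2]],
        individual_ids=lab.individual_ids,
    )


def one_hot(lab: ClassLabeling) -> TargetMatrix:
    """S x n indicator matrix: C[k, i] = 1 iff individual i has label k."""
    S, n = lab.n_classes, lab.n
    C = np.zeros((S, n), dtype=np.int64)
    C[lab.labels, np.arange(n)] = 1
    return TargetMatrix(C)


def _stratified_pick(
    labels: np.ndarray,
    indices: np.ndarray,
    frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick round(frac * n_k) members (min 1) per class from indices."""
    picked: list[np.ndarray] = []
    for k in np.unique(labels[indices]):
        members = indices[labels[indices] == k]
        if members.size < 2:
            raise ValueError(
                f"class {k} has {members.size} member(s); cannot appear in both splits"
            )
        m = max(1, _round_half_up(frac * members.size))
        if m >= members.size:
            m = members.size - 1
        picked.append(rng.choice(members, size=m, replace=False))
    return np.sort(np.concatenate(picked))


def stratified_partitions(
    lab: ClassLabeling,
    R: int,
    test_frac: float = 0.1,
    seed: int | None = 0,
) -> PartitionSet:
    """Generate R class-stratified train/test partitions as a PartitionSet.

    Each partition assigns round(test_frac * n_k) members of every class k
    (minimum one) to the test set, so no class is empty on either side.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not 0.0 < test_frac < 1.0:
        raise ValueError(f"test_frac must be in (0, 1), got {test_frac}")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(lab.n)
    codes = np.ones((lab.n, R), dtype=np.int64)
    for r in range(R):
        test = _stratified_pick(lab.labels, all_idx, test_frac, rng)
        codes[test, r] = 2
    return PartitionSet(codes)


def inner_split(
    train_indices: Sequence[int] | np.ndarray,
    lab: ClassLabeling,
    val_frac: float = 0.12,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split of training indices into (inner-train, validation)."""
    if not 0.0 < val_frac < 1.0:
        raise ValueError(f"val_frac must be in (0, 1), got {val_frac}")
    idx = np.asarray(train_indices, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("empty training index set")
    rng = np.random.default_rng(seed)
    val = _stratified_pick(lab.labels, idx, val_frac, rng)
    train = np.setdiff1d(idx, val)
    return train, val


# ---------------------------------------------------------------------------
# Export


def write_labeling(lab: ClassLabeling, path: str | Path) -> Path:
    """Write (individual_id, label, class_name) rows plus a sidecar metadata file."""
    path = Path(path)
    ids = lab.individual_ids or [str(i) for i in range(lab.n)]
    with open(path, "w") as fh:
        fh.write("individual_id,label,class_name\n")
        for iid, k in zip(ids, lab.labels):
            fh.write(f"{iid},{int(k)},{lab.class_names[int(k)]}\n")
    meta = {
        "scheme": lab.scheme,
        "class_names": lab.class_names,
        "target_class": int(lab.target_class),
        "cut_values": [float(c) for c in lab.cut_values],
    }
    with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_labeling(path: str | Path) -> ClassLabeling:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".meta")) as fh:
        meta = yaml.safe_load(fh)
    ids: list[str] = []
    labels: list[int] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("individual_id"):
            raise ValueError("labeling file missing expected header")
        for line in fh:
            parts = line.rstrip("\n").split(",")
            ids.append(parts[0])
            labels.append(int(parts[1]))
    arr = np.asarray(labels, dtype=np.int64)
    counts = [int((arr == k).sum()) for k in range(len(meta["class_names"]))]
    return ClassLabeling(
        scheme=meta["scheme"],
        class_names=list(meta["class_names"]),
        labels=arr,
        counts=counts,
        target_class=int(meta["target_class"]),
        cut_values=[float(c) for c in meta["cut_values"]],
        individual_ids=ids,
    )


def with_target(lab: ClassLabeling, target: str) -> ClassLabeling:
    """Return a copy of the labeling with a different designated target class."""
    if target not in lab.class_names:
        raise ValueError(f"unknown class {target!r}; have {lab.class_names}")
    return replace(lab, target_class=lab.class_names.index(target))
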