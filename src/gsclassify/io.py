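"""Domain types and delimited-text I/O for genotype, phenotype and partition data.

Tables follow the layout: individuals are rows, markers are columns. Marker
codings are declared explicitly ({0,1} presence/absence or {0,1,2} allele
dosage) and validated at load time; they are never inferred from the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Coding = Literal["01", "012"]
Dialect = Literal["csv", "tsv"]

_DELIMS = {"csv": ",", "tsv": "\t"}

_ALLOWED = {"01": {0, 1}, "012": {0, 1, 2}}


class FormatError(ValueError):
    """Raised when a file violates the expected table format."""


def _delimiter(dialect: Dialect) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class MarkerMatrix:
    """n x p integer-coded genotype matrix with row/column identifiers."""

    individual_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray
    coding: Coding = "012"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = vals.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if len(self.individual_ids) != n:
            raise ValueError("row count does not match number of individual ids")
        if len(self.marker_ids) != p:
            raise ValueError("column count does not match number of marker ids")
        _check_unique(self.individual_ids, "individual")
        _check_unique(self.marker_ids, "marker")
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("marker values must be integers")
        allowed = _ALLOWED[self.coding]
        bad = ~np.isin(vals, list(allowed))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"marker value {vals[i, j]} at individual {self.individual_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r} not in allowed coding {sorted(allowed)}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PhenotypeVector:
    """Continuous trait values aligned to individual identifiers."""

    individual_ids: list[str]
    y: np.ndarray
    trait_name: str = "trait"
    environment: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1:
            raise ValueError("y must be a 1-D vector")
        if len(self.individual_ids) != y.shape[0]:
            raise ValueError("id count does not match phenotype length")
        _check_unique(self.individual_ids, "individual")
        if not np.all(np.isfinite(y)):
            idx = int(np.flatnonzero(~np.isfinite(y))[0])
            raise ValueError(
                f"non-finite phenotype for individual {self.individual_ids[idx]!r}"
            )
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass(frozen=True)
class PartitionSet:
    """n x R matrix of partition codes: 1 = training, 2 = testing."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if not np.issubdtype(codes.dtype, np.integer):
            raise ValueError("partition codes must be integers")
        bad = ~np.isin(codes, (1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"partition code {codes[i, j]} at row {i}, column {j} not in {{1, 2}}"
            )
        for j in range(codes.shape[1]):
            col = codes[:, j]
            if not ((col == 1).any() and (col == 2).any()):
                raise FormatError(
                    f"partition column {j} lacks both training (1) and testing (2) codes"
                )
        object.__setattr__(self, "codes", codes)

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def R(self) -> int:
        return self.codes.shape[1]

    def train_test_indices(self, r: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (training, testing) row indices for partition column r."""
        col = self.codes[:, r]
        return np.flatnonzero(col == 1), np.flatnonzero(col == 2)


@dataclass(frozen=True)
class Dataset:
    """Markers and phenotype on a common, identically ordered set of individuals."""

    markers: MarkerMatrix
    phenotype: PhenotypeVector
    labeling: Optional[object] = field(default=None)

    def __post_init__(self) -> None:
        if self.markers.individual_ids != self.phenotype.individual_ids:
            raise ValueError("marker and phenotype individual ids differ or are misordered")

    @property
    def n(self) -> int:
        return self.markers.n


# ---------------------------------------------------------------------------
# Readers / writers


def read_marker_matrix(
    path: str | Path,
    dialect: Dialect = "csv",
    coding: Coding = "012",
    missing: Literal["fail", "impute_column_mode"] = "fail",
) -> MarkerMatrix:
    """Load a marker table (header of marker ids, first column individual ids).

    ``missing`` controls the policy for empty/NA cells: ``fail`` (default)
    raises, ``impute_column_mode`` replaces each missing call with the most
    frequent value of its column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(dialect), index_col=0, dtype=str)
    ids = [str(i) for i in df.index]
    markers = [str(c) for c in df.columns]
    _check_unique(ids, "individual")
    _check_unique(markers, "marker")

    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=np.int64)
    miss_mask = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() in ("", "NA", "nan"):
                miss_mask[i, j] = True
                values[i, j] = -1
                continue
            text = str(cell).strip()
            try:
                values[i, j] = int(text)
            except ValueError:
                raise FormatError(
                    f"non-integer marker value {text!r} at individual {ids[i]!r}, "
                    f"marker {markers[j]!r}"
                ) from None

    if miss_mask.any():
        if missing == "fail":
            i, j = np.argwhere(miss_mask)[0]
            raise FormatError(
                f"missing genotype at individual {ids[i]!r}, marker {markers[j]!r} "
                "(policy 'fail'; use missing='impute_column_mode' to impute)"
            )
        for j in np.flatnonzero(miss_mask.any(axis=0)):
            col = values[:, j]
            observed = col[~miss_mask[:, j]]
            if observed.size == 0:
                raise FormatError(f"marker {markers[j]!r} has no observed genotypes")
            uniq, counts = np.unique(observed, return_counts=True)
            mode = int(uniq[np.argmax(counts)])
            col[miss_mask[:, j]] = mode
        logger.info("imputed %d missing genotype calls by column mode", int(miss_mask.sum()))

    return MarkerMatrix(ids, markers, values, coding=coding)


def write_marker_matrix(mm: MarkerMatrix, path: str | Path, dialect: Dialect = "csv") -> Path:
    path = Path(path)
    df = pd.DataFrame(mm.values, index=mm.individual_ids, columns=mm.marker_ids)
    df.index.name = "id"
    df.to_csv(path, sep=_delimiter(dialect))
    return path


def read_phenotype(
    path: str | Path,
    dialect: Dialect = "csv",
    trait_name: str | None = None,
    environment: str = "",
) -> PhenotypeVector:
    """Load a phenotype table: first column individual ids, one trait column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(dialect), index_col=0)
    if df.shape[1] < 1:
        raise FormatError("phenotype table has no trait column")
    col = trait_name if trait_name is not None else str(df.columns[0])
    if col not in df.columns:
        raise FormatError(f"trait column {col!r} not found in {list(df.columns)}")
    return PhenotypeVector(
        [str(i) for i in df.index],
        df[col].to_numpy(dtype=float),
        trait_name=col,
        environment=environment,
    )


def write_phenotype(pv: PhenotypeVector, path: str | Path, dialect: Dialect = "csv") -> Path:
    path = Path(path)
    df = pd.DataFrame({pv.trait_name: pv.y}, index=pv.individual_ids)
    df.index.name = "id"
    df.to_csv(path, sep=_delimiter(dialect))
    return path


def write_partition_set(pset: PartitionSet, path: str | Path, dialect: Dialect = "csv") -> Path:
    """Write a partition-index matrix: one row per individual, columns P1..PR."""
    path = Path(path)
    header = [f"P{j + 1}" for j in range(pset.R)]
    df = pd.DataFrame(pset.codes, columns=header)
    df.to_csv(path, sep=_delimiter(dialect), index=False)
    return path


def read_partition_set(path: str | Path, dialect: Dialect = "csv") -> PartitionSet:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = first.strip().split(_delimiter(dialect))
    has_header = not all(t.strip().lstrip("-").isdigit() for t in tokens if t.strip())
    df = pd.read_csv(path, sep=_delimiter(dialect), header=0 if has_header else None)
    arr = df.to_numpy()
    try:
        codes = arr.astype(np.int64)
    except ValueError:
        raise FormatError("partition file contains non-integer entries") from None
    if not np.array_equal(codes, arr.astype(float)):
        raise FormatError("partition file contains non-integer entries")
    return PartitionSet(codes)


def align(markers: MarkerMatrix, phenotype: PhenotypeVector) -> Dataset:
    """Intersect individuals, reordering the phenotype to the marker row order.

    Individuals present in only one component are dropped (count logged).
    """
    phen_pos = {iid: k for k, iid in enumerate(phenotype.individual_ids)}
    keep_rows = [i for i, iid in enumerate(markers.individual_ids) if iid in phen_pos]
    if not keep_rows:
        raise ValueError("no individuals in common between markers and phenotype")
    dropped = (markers.n - len(keep_rows)) + (phenotype.n - len(keep_rows))
    if dropped:
        logger.info("align: dropped %d individuals lacking markers or phenotype", dropped)
    ids = [markers.individual_ids[i] for i in keep_rows]
    mm = MarkerMatrix(ids, list(markers.marker_ids), markers.values[keep_rows], coding=markers.coding)
    order = [phen_pos[iid] for iid in ids]
    pv = PhenotypeVector(ids, phenotype.y[order], phenotype.trait_name, phenotype.environment)
    return Dataset(mm, pv)
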