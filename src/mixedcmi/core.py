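"""Shared data model, distances and preprocessing for mixed-data information estimators.

A *mixed* sample combines qualitative components (finite support, compared
only through exact equality) and quantitative components (real-valued, compared
through metric distances).  Every estimator and test in this package consumes
the same containers defined here: :class:`MixedSample` for the observation
matrix plus its per-column type mask, :class:`VariableBlock` for the X/Y/Z
partition of columns, and :class:`BinPartition` for the grouping of rows by
qualitative value tuples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

QUALITATIVE = "qualitative"
QUANTITATIVE = "quantitative"

__all__ = [
    "QUALITATIVE",
    "QUANTITATIVE",
    "MixedSample",
    "VariableBlock",
    "EstimatorConfig",
    "BinPartition",
    "default_k_rule",
    "linf_distance",
    "adaptive_distance",
    "mixed_metric",
    "rank_transform",
    "rank_transform_sample",
    "partition_by_qualitative",
    "resolve_block",
]


def default_k_rule(n_sub: int) -> int:
    """Neighbour count used for a kNN entropy term on a subsample of size ``n_sub``.

    ``max(floor(n_sub / 10), 1)``: one tenth of the points, never fewer than one.
    """
    return max(n_sub // 10, 1)


@dataclass(frozen=True)
class MixedSample:
    """An n x m observation matrix with a per-column qualitative/quantitative mask.

    Parameters
    ----------
    data
        Matrix of shape ``(n, m)``.  Qualitative columns hold integer category
        codes (stored as floats); quantitative columns hold real values.  No
        missing or non-finite entries are allowed.
    qualitative
        Boolean mask of length ``m``; ``True`` marks a qualitative column.
    """

    data: np.ndarray
    qualitative: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {data.shape}")
        mask = np.asarray(self.qualitative, dtype=bool)
        if mask.shape != (data.shape[1],):
            raise ValueError(
                f"type mask length {mask.shape} does not match {data.shape[1]} columns"
            )
        if data.shape[0] < 1:
            raise ValueError("sample must contain at least one observation")
        if not np.all(np.isfinite(data)):
            raise ValueError("sample contains non-finite entries; missing data is rejected")
        qual = data[:, mask]
        if qual.size and not np.array_equal(qual, np.round(qual)):
            raise ValueError("qualitative columns must hold integer category codes")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "qualitative", mask)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(QUALITATIVE if q else QUANTITATIVE for q in self.qualitative)

    def replace_columns(self, columns: Sequence[int], values: np.ndarray) -> "MixedSample":
        """Return a copy with the given columns overwritten (types unchanged)."""
        data = self.data.copy()
        data[:, list(columns)] = values
        return MixedSample(data, self.qualitative)


@dataclass(frozen=True)
class VariableBlock:
    """A named block of columns (X, Y or Z) split into its type sub-blocks."""

    name: str
    columns: tuple[int, ...]
    t_columns: tuple[int, ...]
    l_columns: tuple[int, ...]

    @classmethod
    def from_sample(cls, name: str, columns: Iterable[int], sample: MixedSample) -> "VariableBlock":
        cols = tuple(int(c) for c in columns)
        if len(set(cols)) != len(cols):
            raise ValueError(f"block {name!r} lists duplicate columns")
        for c in cols:
            if not 0 <= c < sample.m:
                raise IndexError(f"block {name!r}: column {c} out of range for m={sample.m}")
        t_cols = tuple(c for c in cols if not sample.qualitative[c])
        l_cols = tuple(c for c in cols if sample.qualitative[c])
        return cls(name=name, columns=cols, t_columns=t_cols, l_columns=l_cols)


def resolve_block(name: str, block: "VariableBlock | Iterable[int]", sample: MixedSample) -> VariableBlock:
    """Coerce a column list into a :class:`VariableBlock` bound to ``sample``."""
    if isinstance(block, VariableBlock):
        return block
    return VariableBlock.from_sample(name, block, sample)


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunable knobs shared by the entropy primitives and the CMI estimators.

    Attributes
    ----------
    k_rule
        Map from a subsample size to the neighbour count of its kNN entropy
        term.  Chosen per term, per subsample.
    D_l
        Qualitative (0-D) distance used by the kNN baseline estimators.
    tie_floor
        Lower floor applied to the doubled neighbour distances before taking
        logs, guarding ``log 0`` on duplicate points.  ``None`` means
        ``1e-10`` times the data range of the subsample.
    include_volume
        If ``True``, add the unit-ball log-volume ``d * log 2`` to every kNN
        entropy term.  These terms cancel exactly in the CMI combination, so
        the default drops them.
    """

    k_rule: Callable[[int], int] = default_k_rule
    D_l: float = 1.0
    tie_floor: float | None = None
    include_volume: bool = False

    def __post_init__(self) -> None:
        if self.D_l <= 0:
            raise ValueError("D_l must be positive")
        if self.tie_floor is not None and self.tie_floor <= 0:
            raise ValueError("tie_floor must be positive")


@dataclass(frozen=True)
class BinPartition:
    """Rows grouped by their qualitative value tuple, with empirical frequencies."""

    keys: tuple[tuple[float, ...], ...]
    indices: tuple[np.ndarray, ...]
    n: int

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.indices):
            raise ValueError("keys and indices length mismatch")
        total = sum(len(idx) for idx in self.indices)
        if total != self.n:
            raise ValueError("bin sizes do not sum to n")

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(idx) for idx in self.indices], dtype=int)

    @property
    def frequencies(self) -> np.ndarray:
        return self.sizes / self.n

    def items(self):
        return zip(self.keys, self.indices)


def linf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Chebyshev (maximum-norm) distance between two real vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError(f"expected equal-length 1-D vectors, got {a.shape} and {b.shape}")
    return float(np.max(np.abs(a - b)))


def adaptive_distance(zi: np.ndarray, zj: np.ndarray, qualitative: np.ndarray) -> float:
    """Mixed distance for permutation neighbourhoods.

    Coordinate-wise: absolute difference on quantitative components and the
    (0-inf) distance on qualitative components, combined by the maximum.  Any
    qualitative mismatch therefore forces the distance to ``+inf``, confining
    neighbourhoods within a qualitative class.
    """
    zi = np.asarray(zi, dtype=float)
    zj = np.asarray(zj, dtype=float)
    mask = np.asarray(qualitative, dtype=bool)
    if not (zi.shape == zj.shape == mask.shape) or zi.ndim != 1:
        raise ValueError("vectors and type mask must share one dimension")
    if np.any(zi[mask] != zj[mask]):
        return float("inf")
    quant = ~mask
    if not quant.any():
        return 0.0
    return float(np.max(np.abs(zi[quant] - zj[quant])))


def mixed_metric(a: np.ndarray, b: np.ndarray, qualitative: np.ndarray, D_l: float = 1.0) -> float:
    """Mixed distance used by the kNN baseline estimators.

    Absolute difference on quantitative components, the (0-D_l) distance on
    qualitative components, combined by the maximum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = np.asarray(qualitative, dtype=bool)
    if not (a.shape == b.shape == mask.shape) or a.ndim != 1:
        raise ValueError("vectors and type mask must share one dimension")
    per = np.abs(a - b)
    per[mask] = np.where(a[mask] != b[mask], D_l, 0.0)
    return float(per.max()) if per.size else 0.0


def rank_transform(column: np.ndarray) -> np.ndarray:
    """Ranks 1..n with first-appearance tie breaking (every rank distinct)."""
    column = np.asarray(column, dtype=float)
    if column.ndim != 1 or column.size < 1:
        raise ValueError("rank_transform expects a nonempty 1-D column")
    return rankdata(column, method="ordinal").astype(float)


def rank_transform_sample(sample: MixedSample) -> MixedSample:
    """Rank-transform every quantitative column of a sample; qualitative ones pass through."""
    data = sample.data.copy()
    for c in np.flatnonzero(~sample.qualitative):
        data[:, c] = rank_transform(data[:, c])
    return MixedSample(data, sample.qualitative)


def partition_by_qualitative(sample: MixedSample, l_columns: Iterable[int]) -> BinPartition:
    """Group rows by their tuple of values on the given qualitative columns.

    With an empty column set the partition is the single bin holding every row
    (vacuous conditioning, frequency 1).
    """
    l_columns = tuple(int(c) for c in l_columns)
    for c in l_columns:
        if not sample.qualitative[c]:
            raise TypeError(f"column {c} is quantitative; cannot partition on it")
    n = sample.n
    if not l_columns:
        return BinPartition(keys=((),), indices=(np.arange(n),), n=n)
    sub = sample.data[:, l_columns]
    uniq, inverse = np.unique(sub, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(len(uniq) + 1))
    indices = tuple(order[bounds[b] : bounds[b + 1]] for b in range(len(uniq)))
    keys = tuple(tuple(row) for row in uniq)
    return BinPartition(keys=keys, indices=indices, n=n)
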