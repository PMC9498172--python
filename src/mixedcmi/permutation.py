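"""Permutation conditional-independence tests: GloT, LocT and LocAT.

All three tests share the same recipe: compute the observed statistic
I(X;Y|Z) with a pluggable estimator, rebuild it B times on replicates
(X_{pi_b(i)}, Y_i, Z_i) drawn under the null, and report

    p = (1/B) * #{b : I_permuted_b >= I_observed}.

They differ only in how the index maps pi_b are drawn:

* GloT   - pi_b is a uniform permutation of all rows (global shuffle; breaks
  the X-Z dependence too, which hurts level and power when Z matters).
* LocT   - pi_b(i) is drawn from the k_perm-nearest neighbours of Z_i under a
  mixed distance that is (0-inf) on qualitative components.  When fewer than
  k_perm points share Z_i's qualitative values the k-th distance is infinite
  and the neighbourhood silently degrades to the whole sample.
* LocAT  - as LocT but with a per-point adaptive neighbour count
  k_i = min(k_perm, #points sharing Z_i's qualitative values), so the
  neighbourhood never escapes the qualitative class.

Quantitative columns are rank-transformed once before testing (default on),
putting all components on the same scale and removing ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .baselines import METHODS as BASELINE_METHODS
from .baselines import baseline_estimate
from .cmih import CmihPermutationStatistic, cmih
from .core import (
    EstimatorConfig,
    MixedSample,
    VariableBlock,
    partition_by_qualitative,
    rank_transform_sample,
    resolve_block,
)

__all__ = [
    "SCHEMES",
    "TestConfig",
    "NeighborhoodSet",
    "TestResult",
    "build_neighborhoods",
    "draw_local_permutation",
    "run_test",
]

SCHEMES = ("glot", "loct", "locat")


@dataclass(frozen=True)
class TestConfig:
    """Configuration of a permutation test.

    B: number of permuted replicates; k_perm: neighbourhood size
    hyper-parameter; scheme: one of ``glot``, ``loct``, ``locat``;
    rank_transform: rank-transform quantitative columns before testing;
    seed: RNG seed (each replicate uses an independent deterministic
    substream, so results do not depend on evaluation order).
    """

    __test__ = False  # not a pytest class, despite the name

    B: int = 1000
    k_perm: int = 5
    scheme: str = "locat"
    rank_transform: bool = True
    seed: int | None = None
    estimator_config: EstimatorConfig = field(default_factory=EstimatorConfig)

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.k_perm < 1:
            raise ValueError("k_perm must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")


@dataclass(frozen=True)
class NeighborhoodSet:
    """Per-point donor neighbourhoods in Z-space.

    ``neighborhoods[i]`` is the index set {j : D(Z_j, Z_i) <= d_i}, which
    always contains i itself; ``k`` the per-point neighbour count actually
    used; ``d`` the distance to the k-th neighbour (inf when the neighbourhood
    degraded to the full sample); ``n_class`` the number of points sharing
    i's qualitative Z values (n when Z has no qualitative component).
    """

    neighborhoods: tuple[np.ndarray, ...]
    k: np.ndarray
    d: np.ndarray
    n_class: np.ndarray
    # flattened ragged layout for vectorised donor draws
    _flat: np.ndarray = field(repr=False, default=None)
    _offsets: np.ndarray = field(repr=False, default=None)
    _lengths: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        lengths = np.array([len(a) for a in self.neighborhoods], dtype=np.intp)
        offsets = np.concatenate([[0], np.cumsum(lengths[:-1])])
        flat = (
            np.concatenate(self.neighborhoods)
            if self.neighborhoods
            else np.empty(0, dtype=np.intp)
        )
        object.__setattr__(self, "_flat", flat.astype(np.intp))
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_lengths", lengths)

    def __len__(self) -> int:
        return len(self.neighborhoods)


def build_neighborhoods(
    sample: MixedSample,
    z_columns: Iterable[int],
    k_perm: int,
    adaptive: bool = True,
) -> NeighborhoodSet:
    """Donor neighbourhoods of every point in Z-space (Algorithmic core of LocT/LocAT).

    With ``adaptive=True`` (LocAT) the neighbour count is clamped to the size
    of the point's qualitative Z class, so the k-th distance is always finite.
    With ``adaptive=False`` (LocT) a fixed ``k_perm`` is used; classes smaller
    than ``k_perm`` then make the k-th distance infinite and the neighbourhood
    becomes the whole sample.  With an empty Z every neighbourhood is the whole
    sample, which reduces any local scheme to the global test.
    """
    z_columns = tuple(int(c) for c in z_columns)
    n = sample.n
    zb = resolve_block("Z", z_columns, sample)
    full = np.arange(n)

    if not z_columns:
        nb = tuple(full for _ in range(n))
        return NeighborhoodSet(
            neighborhoods=nb,
            k=np.full(n, n, dtype=int),
            d=np.zeros(n),
            n_class=np.full(n, n, dtype=int),
        )

    part = partition_by_qualitative(sample, zb.l_columns)
    neighborhoods: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    k_arr = np.zeros(n, dtype=int)
    d_arr = np.zeros(n)
    class_arr = np.zeros(n, dtype=int)

    for _, idx in part.items():
        c = len(idx)
        class_arr[idx] = c if zb.l_columns else n
        if zb.l_columns and adaptive:
            k_i = min(k_perm, c)
        else:
            k_i = min(k_perm, n)  # k cannot exceed the sample size
        if k_i > c:
            # fixed-k scheme, class smaller than k: the k-th neighbour sits at
            # distance inf, so the <= rule admits every point
            for i in idx:
                neighborhoods[i] = full
                k_arr[i] = k_i
                d_arr[i] = np.inf
            continue
        if zb.t_columns:
            pts = sample.data[np.ix_(idx, list(zb.t_columns))]
            dist = np.max(np.abs(pts[:, None, :] - pts[None, :, :]), axis=2)
        else:
            dist = np.zeros((c, c))
        # the point itself (distance 0) counts among the k_i nearest
        d_i = np.partition(dist, k_i - 1, axis=1)[:, k_i - 1]
        for row, i in enumerate(idx):
            neighborhoods[i] = idx[dist[row] <= d_i[row]]
            k_arr[i] = k_i
            d_arr[i] = d_i[row]

    return NeighborhoodSet(
        neighborhoods=tuple(neighborhoods), k=k_arr, d=d_arr, n_class=class_arr
    )


def draw_local_permutation(
    neighborhoods: NeighborhoodSet, rng: np.random.Generator
) -> np.ndarray:
    """Index map pi with pi(i) uniform on N_i, independent across i (with replacement)."""
    picks = rng.integers(0, neighborhoods._lengths)
    return neighborhoods._flat[neighborhoods._offsets + picks]


@dataclass(frozen=True)
class TestResult:
    """Observed statistic, the B permuted statistics, and the p-value.

    ``p_value = (1/B) * #{b : permuted_b >= statistic}`` exactly, hence always
    a multiple of 1/B in [0, 1] (0 is attainable: no add-one smoothing).
    """

    __test__ = False  # not a pytest class, despite the name

    statistic: float
    permuted: np.ndarray
    p_value: float
    config: TestConfig


def _make_statistic(
    estimator: "str | Callable",
    sample: MixedSample,
    x: VariableBlock,
    y: VariableBlock,
    z: VariableBlock,
    config: TestConfig,
):
    """Return (observed_value, permuted_evaluator(pi) -> value)."""
    if callable(estimator):
        def permuted(pi: np.ndarray) -> float:
            cols = list(x.columns)
            perm = sample.replace_columns(cols, sample.data[np.ix_(pi, cols)])
            return float(estimator(perm, x.columns, y.columns, z.columns))

        return float(estimator(sample, x.columns, y.columns, z.columns)), permuted

    name = estimator.lower()
    if name == "cmih":
        ev = CmihPermutationStatistic(sample, x, y, z, config.estimator_config)
        return ev.observed(), ev.permuted
    if name in BASELINE_METHODS:
        # MS/RAVK/FP keep their own (0-D_l) metric inside the estimator even
        # though the permutation neighbourhoods use (0-inf)
        def stat(s: MixedSample, xc, yc, zc) -> float:
            return baseline_estimate(s, xc, yc, zc, method=name, config=config.estimator_config)

        def permuted(pi: np.ndarray) -> float:
            cols = list(x.columns)
            perm = sample.replace_columns(cols, sample.data[np.ix_(pi, cols)])
            return stat(perm, x.columns, y.columns, z.columns)

        return stat(sample, x.columns, y.columns, z.columns), permuted
    raise ValueError(f"unknown estimator {estimator!r}")


def run_test(
    sample: MixedSample,
    x: "VariableBlock | Iterable[int]",
    y: "VariableBlock | Iterable[int]",
    z: "VariableBlock | Iterable[int]" = (),
    estimator: "str | Callable" = "cmih",
    config: TestConfig | None = None,
) -> TestResult:
    """Permutation test of H0: X independent of Y given Z.

    ``estimator`` is ``"cmih"``, ``"fp"``, ``"ravk"``, ``"ms"`` or any
    callable ``(sample, x_cols, y_cols, z_cols) -> float``.  Only the X
    columns are ever altered in the permuted replicates.
    """
    config = config or TestConfig()
    work = rank_transform_sample(sample) if config.rank_transform else sample
    xb = resolve_block("X", x, work)
    yb = resolve_block("Y", y, work)
    zb = resolve_block("Z", z, work)
    n = work.n

    observed, permuted_stat = _make_statistic(estimator, work, xb, yb, zb, config)

    if config.scheme == "glot" or not zb.columns:
        neighborhoods = None
    else:
        neighborhoods = build_neighborhoods(
            work, zb.columns, config.k_perm, adaptive=(config.scheme == "locat")
        )

    seed_seq = np.random.SeedSequence(config.seed)
    child_seeds = seed_seq.spawn(config.B)
    permuted = np.empty(config.B)
    for b in range(config.B):
        rng = np.random.default_rng(child_seeds[b])
        if neighborhoods is None:
            pi = rng.permutation(n)
        else:
            pi = draw_local_permutation(neighborhoods, rng)
        permuted[b] = permuted_stat(pi)

    p_value = float(np.count_nonzero(permuted >= observed)) / config.B
    return TestResult(statistic=float(observed), permuted=permuted, p_value=p_value, config=config)
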