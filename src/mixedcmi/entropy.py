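"""Entropy primitives: plug-in entropy of qualitative tuples and
Kozachenko-Leonenko kNN entropy of quantitative vectors.

The hybrid CMI estimator decomposes conditional mutual information into
entropies that condition only on qualitative components.  Each such entropy is
either a discrete plug-in entropy over empirical bin frequencies, or a
bin-weighted sum of Kozachenko-Leonenko differential-entropy estimates of the
quantitative sub-vector within each qualitative bin.

All entropies are in nats.  The kNN terms use the Chebyshev (maximum-norm)
distance; the unit-ball log-volume term ``d log 2`` is dropped by default
because it cancels exactly in the CMI combination (the quantitative dimensions
satisfy ``d_xz + d_yz - d_xyz - d_z = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .core import BinPartition, EstimatorConfig, MixedSample

__all__ = [
    "KnnEntropyTerm",
    "plugin_entropy",
    "knn_entropy_term",
    "kl_knn_entropy",
    "conditional_knn_entropy",
]

# below this size an all-pairs distance matrix beats building a KD-tree
_BRUTE_FORCE_LIMIT = 96


@dataclass(frozen=True)
class KnnEntropyTerm:
    """One Kozachenko-Leonenko entropy term with its ingredients exposed.

    ``xi`` holds, per point, twice the Chebyshev distance to the point's
    k-th nearest neighbour within the subsample.
    """

    n_sub: int
    k_sub: int
    d_sub: int
    xi: np.ndarray
    value: float


def plugin_entropy(partition: BinPartition) -> float:
    """Discrete plug-in entropy -sum p log p of the partition's bin frequencies."""
    p = partition.frequencies
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _knn_radii(points: np.ndarray, k: int) -> np.ndarray:
    """Chebyshev distance of every point to its k-th nearest neighbour (self excluded)."""
    n = points.shape[0]
    if n <= _BRUTE_FORCE_LIMIT:
        dist = np.max(np.abs(points[:, None, :] - points[None, :, :]), axis=2)
        np.fill_diagonal(dist, np.inf)
        return np.partition(dist, k - 1, axis=1)[:, k - 1]
    tree = cKDTree(points)
    # k+1 smallest distances including the query point itself (distance 0)
    dist, _ = tree.query(points, k=k + 1, p=np.inf)
    return dist[:, -1]


def knn_entropy_term(
    points: np.ndarray, k: int, config: EstimatorConfig | None = None
) -> KnnEntropyTerm:
    """Kozachenko-Leonenko entropy of a set of quantitative vectors.

    ``psi(n) - psi(k) + (d/n) * sum_i log xi_i`` with ``xi_i`` twice the
    Chebyshev distance of point ``i`` to its k-th nearest neighbour.  The
    log-volume term ``d log 2`` is added only when ``config.include_volume``.
    Duplicate points would give ``xi = 0``; ``xi`` is floored at
    ``config.tie_floor`` (default: 1e-10 times the data range) so the log stays
    finite.  Rank-transforming the columns beforehand avoids ties altogether.
    """
    config = config or EstimatorConfig()
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    points = np.ascontiguousarray(points)
    if points.shape[1] == 0:
        raise ValueError("points must have dimension >= 1")
    n, d = points.shape
    if n < 2:
        raise ValueError("kNN entropy needs at least two points")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    radii = _knn_radii(points, k)
    xi = 2.0 * radii
    floor = config.tie_floor
    if floor is None:
        data_range = float(points.max() - points.min())
        floor = 1e-10 * data_range if data_range > 0 else 1e-10
    xi = np.maximum(xi, floor)
    value = digamma(n) - digamma(k) + d * np.mean(np.log(xi))
    if config.include_volume:
        value += d * np.log(2.0)
    return KnnEntropyTerm(n_sub=n, k_sub=k, d_sub=d, xi=xi, value=float(value))


def kl_knn_entropy(
    points: np.ndarray, k: int, config: EstimatorConfig | None = None
) -> float:
    """Value of :func:`knn_entropy_term` (nats)."""
    return knn_entropy_term(points, k, config).value


def conditional_knn_entropy(
    sample: MixedSample,
    t_columns: Iterable[int],
    partition: BinPartition,
    config: EstimatorConfig | None = None,
) -> float:
    """Bin-weighted kNN entropy of quantitative columns given a qualitative partition.

    ``sum_b p_b * H_knn(rows of bin b)`` where each bin picks its own
    neighbour count ``k = clamp(k_rule(n_b), 1, n_b - 1)``.  Bins of size one
    have no neighbour and contribute 0 with their weight retained, keeping the
    weights a convex combination.  An empty quantitative column set yields 0.
    """
    config = config or EstimatorConfig()
    t_columns = tuple(int(c) for c in t_columns)
    for c in t_columns:
        if sample.qualitative[c]:
            raise TypeError(f"column {c} is qualitative; kNN entropy needs quantitative columns")
    if not t_columns:
        return 0.0
    total = 0.0
    cols = list(t_columns)
    for idx, p_b in zip(partition.indices, partition.frequencies):
        n_b = len(idx)
        if n_b < 2:
            continue  # size-1 bin: no neighbour, contributes 0
        k = min(max(config.k_rule(n_b), 1), n_b - 1)
        pts = sample.data[np.ix_(idx, cols)]
        total += p_b * kl_knn_entropy(pts, k, config)
    return float(total)
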