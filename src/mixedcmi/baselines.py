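"""kNN baseline CMI estimators: Frenzel-Pompe (FP), Rahimzamani et al. (RAVK)
and Mesner-Shalizi (MS).

All three share the form

    I(X;Y|Z) = (1/n) sum_i  psi(k_i) - f(n_XZ,i) - f(n_YZ,i) + f(n_Z,i)

where the per-point radius is the Chebyshev distance to the k-th nearest
neighbour in the full joint (X,Y,Z) space under a mixed metric (absolute
difference on quantitative components, the (0-D_l) distance on qualitative
ones), and n_W,i counts the points of the marginal subspace W inside that
radius.  The methods differ in the counting inequality, in f and in whether
k_i is fixed (FP) or the realised in-ball count (RAVK, MS).

MS degenerates to exactly 0 whenever every radius reaches D_l on a sample
whose Y and Z blocks are qualitative: all four per-point terms then cancel.
The estimators here exist to benchmark against CMIh and to reproduce that
failure mode.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.special import digamma

from .core import EstimatorConfig, MixedSample, mixed_metric, resolve_block

__all__ = ["count_strict", "count_nonstrict", "pairwise_mixed_distances", "baseline_estimate"]

METHODS = ("fp", "ravk", "ms")


def pairwise_mixed_distances(
    data: np.ndarray, columns: Iterable[int], qualitative: np.ndarray, D_l: float
) -> np.ndarray:
    """Full n x n mixed-metric distance matrix over the given columns.

    Empty column sets give the all-zero matrix (every point at distance 0, the
    convention for a 0-dimensional subspace).
    """
    n = data.shape[0]
    dist = np.zeros((n, n))
    for c in columns:
        v = data[:, c]
        if qualitative[c]:
            dc = (v[:, None] != v[None, :]) * D_l
        else:
            dc = np.abs(v[:, None] - v[None, :])
        np.maximum(dist, dc, out=dist)
    return dist


def _distances_from(i: int, points: np.ndarray, qualitative, D_l: float) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if qualitative is None:
        qualitative = np.zeros(points.shape[1], dtype=bool)
    return np.array(
        [mixed_metric(points[i], points[j], qualitative, D_l) for j in range(len(points))]
    )


def count_strict(
    i: int, points: np.ndarray, radius: float, qualitative=None, D_l: float = 1.0
) -> int:
    """Number of points j != i at mixed distance strictly below ``radius``."""
    d = _distances_from(i, points, qualitative, D_l)
    d[i] = np.inf
    return int(np.sum(d < radius))


def count_nonstrict(
    i: int, points: np.ndarray, radius: float, qualitative=None, D_l: float = 1.0
) -> int:
    """Number of points j != i at mixed distance at most ``radius`` (boundary included)."""
    d = _distances_from(i, points, qualitative, D_l)
    d[i] = np.inf
    return int(np.sum(d <= radius))


def baseline_estimate(
    sample: MixedSample,
    x: Iterable[int],
    y: Iterable[int],
    z: Iterable[int] = (),
    method: str = "ms",
    k: int | None = None,
    config: EstimatorConfig | None = None,
) -> float:
    """FP / RAVK / MS conditional mutual information estimate (nats).

    Parameters
    ----------
    method
        ``"fp"``: fixed ``k_i = k``, strict counts floored at 1,
        ``f = psi(c + 1)``.
        ``"ravk"``: ``k_i`` = non-strict in-ball count in the joint space,
        ``f = log(c + 1)``.
        ``"ms"``: as RAVK but ``f = psi(c)`` with all counts clamped to >= 1
        so the digamma is defined.
    k
        Neighbour order defining the per-point radius; default
        ``max(floor(n/10), 1)``.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    config = config or EstimatorConfig()
    xb = resolve_block("X", x, sample)
    yb = resolve_block("Y", y, sample)
    zb = resolve_block("Z", z, sample)
    n = sample.n
    if k is None:
        k = max(n // 10, 1)
    if k < 1 or n < k + 1:
        raise ValueError(f"need 1 <= k <= n - 1, got k={k}, n={n}")

    data, qual = sample.data, sample.qualitative
    d_full = pairwise_mixed_distances(data, xb.columns + yb.columns + zb.columns, qual, config.D_l)
    np.fill_diagonal(d_full, np.inf)
    # per-point radius: exact k-th order statistic of distances to the others
    rho = np.partition(d_full, k - 1, axis=1)[:, k - 1]

    def counts(columns: tuple[int, ...], strict: bool) -> np.ndarray:
        d_w = pairwise_mixed_distances(data, columns, qual, config.D_l)
        np.fill_diagonal(d_w, np.inf)
        if strict:
            return np.sum(d_w < rho[:, None], axis=1)
        return np.sum(d_w <= rho[:, None], axis=1)

    strict = method == "fp"
    n_xz = counts(xb.columns + zb.columns, strict)
    n_yz = counts(yb.columns + zb.columns, strict)
    n_z = counts(zb.columns, strict)

    if method == "fp":
        # floor strict counts at 1 (zero counts occur at zero radius)
        n_xz, n_yz, n_z = (np.maximum(c, 1) for c in (n_xz, n_yz, n_z))
        terms = digamma(k) - digamma(n_xz + 1) - digamma(n_yz + 1) + digamma(n_z + 1)
    else:
        k_i = np.sum(d_full <= rho[:, None], axis=1)
        if method == "ravk":
            terms = digamma(k_i) - np.log(n_xz + 1) - np.log(n_yz + 1) + np.log(n_z + 1)
        else:  # ms
            n_xz, n_yz, n_z, k_i = (np.maximum(c, 1) for c in (n_xz, n_yz, n_z, k_i))
            terms = digamma(k_i) - digamma(n_xz) - digamma(n_yz) + digamma(n_z)
    return float(np.mean(terms))
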