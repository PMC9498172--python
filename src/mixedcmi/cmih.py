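"""The hybrid conditional-mutual-information estimator CMIh.

CMIh writes I(X;Y|Z) as eight entropy terms in which conditioning only ever
involves qualitative components::

    I(X;Y|Z) =  H(Xt,Zt|Xl,Zl) + H(Yt,Zt|Yl,Zl) - H(Xt,Yt,Zt|Xl,Yl,Zl) - H(Zt|Zl)
              + H(Xl,Zl)       + H(Yl,Zl)       - H(Xl,Yl,Zl)          - H(Zl)

(superscript t = quantitative sub-vector, l = qualitative sub-vector).  The
four qualitative terms are discrete plug-in entropies; the four conditional
terms are bin-weighted Kozachenko-Leonenko kNN entropies, each bin choosing
its own neighbour count from its own subsample size.  The estimate may be
negative in finite samples; no clamp is applied, because permutation tests
need the raw statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import (
    EstimatorConfig,
    MixedSample,
    VariableBlock,
    partition_by_qualitative,
    resolve_block,
)
from .entropy import conditional_knn_entropy, plugin_entropy

__all__ = ["CmiEstimate", "cmih", "CmihPermutationStatistic"]


@dataclass(frozen=True)
class CmiEstimate:
    """A CMI estimate with its per-term entropy breakdown (all in nats).

    ``terms`` maps e.g. ``"H(XtZt|XlZl)"`` / ``"H(XlZl)"`` to the term value;
    ``value`` equals the signed sum of the eight terms exactly.
    """

    value: float
    terms: dict[str, float]
    config: EstimatorConfig


def _check_blocks(x: VariableBlock, y: VariableBlock, z: VariableBlock) -> None:
    seen: set[int] = set()
    for block in (x, y, z):
        overlap = seen.intersection(block.columns)
        if overlap:
            raise ValueError(f"blocks overlap on columns {sorted(overlap)}")
        seen.update(block.columns)
    if not x.columns or not y.columns:
        raise ValueError("X and Y blocks must be nonempty")


def _entropy_pair(
    sample: MixedSample,
    t_cols: tuple[int, ...],
    l_cols: tuple[int, ...],
    config: EstimatorConfig,
) -> tuple[float, float]:
    """(plug-in entropy of the qualitative columns,
    conditional kNN entropy of the quantitative columns given them)."""
    part = partition_by_qualitative(sample, l_cols)
    h_qual = plugin_entropy(part)
    h_quant = conditional_knn_entropy(sample, t_cols, part, config)
    return h_qual, h_quant


def cmih(
    sample: MixedSample,
    x: "VariableBlock | Iterable[int]",
    y: "VariableBlock | Iterable[int]",
    z: "VariableBlock | Iterable[int]" = (),
    config: EstimatorConfig | None = None,
) -> CmiEstimate:
    """Estimate I(X;Y|Z) on a mixed sample (Z may be empty, giving plain MI).

    Parameters
    ----------
    sample
        The observations with their type mask.
    x, y, z
        Column blocks (``VariableBlock`` or plain column index lists);
        pairwise disjoint.
    config
        Estimator configuration; defaults to ``k = max(floor(n_sub/10), 1)``
        per entropy term.
    """
    config = config or EstimatorConfig()
    xb = resolve_block("X", x, sample)
    yb = resolve_block("Y", y, sample)
    zb = resolve_block("Z", z, sample)
    _check_blocks(xb, yb, zb)
    any_quant = xb.t_columns or yb.t_columns or zb.t_columns
    if sample.n < 2 and any_quant:
        raise ValueError("need n >= 2 to estimate entropies of quantitative components")

    groups = {
        "XZ": (xb.t_columns + zb.t_columns, xb.l_columns + zb.l_columns),
        "YZ": (yb.t_columns + zb.t_columns, yb.l_columns + zb.l_columns),
        "XYZ": (
            xb.t_columns + yb.t_columns + zb.t_columns,
            xb.l_columns + yb.l_columns + zb.l_columns,
        ),
        "Z": (zb.t_columns, zb.l_columns),
    }
    terms: dict[str, float] = {}
    for label, (t_cols, l_cols) in groups.items():
        h_qual, h_quant = _entropy_pair(sample, t_cols, l_cols, config)
        terms[f"H({label}t|{label}l)"] = h_quant
        terms[f"H({label}l)"] = h_qual
    value = (
        terms["H(XZt|XZl)"]
        + terms["H(YZt|YZl)"]
        - terms["H(XYZt|XYZl)"]
        - terms["H(Zt|Zl)"]
        + terms["H(XZl)"]
        + terms["H(YZl)"]
        - terms["H(XYZl)"]
        - terms["H(Zl)"]
    )
    return CmiEstimate(value=float(value), terms=terms, config=config)


class CmihPermutationStatistic:
    """CMIh evaluated repeatedly on samples that differ only in the X rows.

    In a permutation test only the X columns change between replicates, so the
    four entropy terms built from (Y, Z) alone are computed once and cached;
    each permuted replicate recomputes only the X-dependent terms.
    """

    def __init__(
        self,
        sample: MixedSample,
        x: "VariableBlock | Iterable[int]",
        y: "VariableBlock | Iterable[int]",
        z: "VariableBlock | Iterable[int]" = (),
        config: EstimatorConfig | None = None,
    ) -> None:
        self.config = config or EstimatorConfig()
        self.sample = sample
        self.x = resolve_block("X", x, sample)
        self.y = resolve_block("Y", y, sample)
        self.z = resolve_block("Z", z, sample)
        _check_blocks(self.x, self.y, self.z)
        yz_qual, yz_quant = _entropy_pair(
            sample,
            self.y.t_columns + self.z.t_columns,
            self.y.l_columns + self.z.l_columns,
            self.config,
        )
        z_qual, z_quant = _entropy_pair(
            sample, self.z.t_columns, self.z.l_columns, self.config
        )
        self._fixed = yz_quant - z_quant + yz_qual - z_qual

    def _x_terms(self, sample: MixedSample) -> float:
        xz_qual, xz_quant = _entropy_pair(
            sample,
            self.x.t_columns + self.z.t_columns,
            self.x.l_columns + self.z.l_columns,
            self.config,
        )
        xyz_qual, xyz_quant = _entropy_pair(
            sample,
            self.x.t_columns + self.y.t_columns + self.z.t_columns,
            self.x.l_columns + self.y.l_columns + self.z.l_columns,
            self.config,
        )
        return xz_quant - xyz_quant + xz_qual - xyz_qual

    def observed(self) -> float:
        return float(self._fixed + self._x_terms(self.sample))

    def permuted(self, pi: np.ndarray) -> float:
        """Statistic on the replicate (X_{pi(i)}, Y_i, Z_i)."""
        cols = list(self.x.columns)
        permuted = self.sample.replace_columns(cols, self.sample.data[np.ix_(pi, cols)])
        return float(self._fixed + self._x_terms(permuted))
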