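"""Tabular ingestion and result serialization.

Input is delimited text (CSV/TSV) with a header row plus a column
specification declaring, per column, its type (qualitative | quantitative)
and block membership (X | Y | Z | ignore).  Qualitative labels are mapped to
integer codes in sorted lexical order of their string representation, so the
coding is stable across runs.  Missing values are rejected outright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cmih import CmiEstimate
from .core import MixedSample, VariableBlock
from .permutation import TestResult

__all__ = ["ColumnSpec", "load_column_spec", "read_table", "write_result", "result_to_dict"]

_TYPES = ("qualitative", "quantitative")
_BLOCKS = ("X", "Y", "Z", "ignore")


@dataclass(frozen=True)
class ColumnSpec:
    """Declared type and block membership of one input column."""

    name: str
    type: str
    block: str

    def __post_init__(self) -> None:
        if self.type not in _TYPES:
            raise ValueError(f"column {self.name!r}: type must be one of {_TYPES}")
        if self.block not in _BLOCKS:
            raise ValueError(f"column {self.name!r}: block must be one of {_BLOCKS}")


def load_column_spec(path) -> list[ColumnSpec]:
    """Read a YAML column spec: ``{column: {type: ..., block: ...}, ...}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("column spec must be a mapping of column name -> {type, block}")
    specs = []
    for name, entry in raw.items():
        if not isinstance(entry, dict) or "type" not in entry or "block" not in entry:
            raise ValueError(f"column {name!r}: expected a mapping with 'type' and 'block'")
        specs.append(ColumnSpec(name=str(name), type=entry["type"], block=entry["block"]))
    return specs


def read_table(path, column_spec: list[ColumnSpec], sep: str | None = None):
    """Load a delimited table into a :class:`MixedSample` plus X/Y/Z blocks.

    Returns ``(sample, blocks)`` with ``blocks`` a dict mapping block name to
    a :class:`VariableBlock`.  Raises on missing cells (naming row and
    column), on spec columns absent from the file, and on blocks X or Y being
    empty.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    used = [s for s in column_spec if s.block != "ignore"]
    missing_cols = [s.name for s in used if s.name not in frame.columns]
    if missing_cols:
        raise KeyError(f"columns {missing_cols} declared in spec but absent from {path.name}")
    names = [s.name for s in used]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"columns {sorted(dupes)} assigned to more than one block")

    columns, qualitative = [], []
    for spec in used:
        raw = frame[spec.name]
        na = raw.isna() | (raw.str.strip() == "")
        if na.any():
            row = int(np.flatnonzero(na.to_numpy())[0])
            raise ValueError(f"missing value at row {row}, column {spec.name!r}")
        if spec.type == "qualitative":
            labels = sorted(raw.unique())
            coding = {label: code for code, label in enumerate(labels)}
            columns.append(raw.map(coding).to_numpy(dtype=float))
            qualitative.append(True)
        else:
            try:
                columns.append(raw.astype(float).to_numpy())
            except ValueError as exc:
                raise ValueError(f"column {spec.name!r} is not numeric: {exc}") from None
            qualitative.append(False)

    sample = MixedSample(np.column_stack(columns), np.array(qualitative))
    blocks = {}
    for block_name in ("X", "Y", "Z"):
        cols = [i for i, s in enumerate(used) if s.block == block_name]
        blocks[block_name] = VariableBlock.from_sample(block_name, cols, sample)
    if not blocks["X"].columns or not blocks["Y"].columns:
        raise ValueError("blocks X and Y must each contain at least one column")
    return sample, blocks


def result_to_dict(result, seed=None) -> dict:
    """JSON-serializable view of a CmiEstimate or TestResult."""
    from . import __version__

    if isinstance(result, CmiEstimate):
        payload = {
            "kind": "cmi_estimate",
            "value": result.value,
            "terms": dict(result.terms),
        }
    elif isinstance(result, TestResult):
        cfg = result.config
        payload = {
            "kind": "test_result",
            "statistic": result.statistic,
            "p_value": result.p_value,
            "B": cfg.B,
            "k_perm": cfg.k_perm,
            "scheme": cfg.scheme,
            "rank_transform": cfg.rank_transform,
            "permuted": [float(v) for v in result.permuted],
        }
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    payload["seed"] = seed
    payload["version"] = __version__
    return payload


def write_result(result, path_or_stream, seed=None) -> None:
    """Serialize a result as round-trippable JSON at full float precision."""
    payload = result_to_dict(result, seed=seed)
    if hasattr(path_or_stream, "write"):
        json.dump(payload, path_or_stream, indent=2)
        path_or_stream.write("\n")
    else:
        with open(path_or_stream, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
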