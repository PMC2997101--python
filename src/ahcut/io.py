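"""File round-tripping: distance/expression TSVs, partitions, Newick, JSON.

Formats
-------
distance matrix
    TSV or CSV; first row and first column are labels, numeric body,
    symmetric with zero diagonal.
expression matrix
    TSV/CSV; first column gene labels, header row sample labels.
partition
    Two-column TSV (label, side in {1, 2}) plus a JSON objective record.
dendrogram
    Newick (leaf labels verbatim, quoted when they contain reserved
    characters; internal-node comments carry the split value) or a JSON
    tree dump.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .distances import ExpressionMatrix
from .errors import GraphValidationError
from .graph import Bipartition

__all__ = [
    "read_distance_matrix",
    "write_distance_matrix",
    "read_expression",
    "write_expression",
    "write_partition",
    "read_partition",
    "newick_string",
    "write_truth_labels",
]

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    """Labelled square distance table from TSV/CSV (validation happens in
    ``build_graph``)."""
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:
        raise GraphValidationError(f"cannot parse distance matrix {path}: {exc}") from exc
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    return frame


def write_distance_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep=_sep_for(path), float_format="%.12g")


def read_expression(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ExpressionMatrix.from_frame(frame)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.10g")


def write_partition(part: Bipartition, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Two-column (label, side) TSV plus an objective-breakdown JSON record."""
    with open(tsv_path, "w") as fh:
        fh.write("label\tside\n")
        for lab in part.labels:
            fh.write(f"{lab}\t{part.side[lab]}\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(part.breakdown.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_partition(tsv_path: str | Path) -> dict[str, int]:
    """Label -> group mapping from a two-column TSV (partition or level file)."""
    frame = pd.read_csv(tsv_path, sep="\t", dtype={0: str})
    label_col, group_col = frame.columns[:2]
    return {str(k): int(v) for k, v in zip(frame[label_col], frame[group_col])}


def write_truth_labels(truth: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for lab, grp in truth.items():
            fh.write(f"{lab}\t{grp}\n")


def _quote_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(node, annotate: bool = True) -> str:
    """Serialise a dendrogram to Newick; deterministic for a fixed tree."""

    def render(nd) -> str:
        if nd.is_leaf:
            return _quote_label(nd.members[0])
        left, right = nd.children
        comment = f"[&split_value={nd.split_value:.12g}]" if annotate else ""
        return f"({render(left)},{render(right)}){comment}"

    return render(node) + ";"
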