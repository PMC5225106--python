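"""Control-centered hierarchical clustering for heatmap-style summaries.

Values are centered per feature by the mean of the control (CK)
samples, so every number reads as deviation from the unstressed state;
features and samples are then clustered agglomeratively (correlation
distance, average linkage by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

from .io import NormalizedTable

logger = logging.getLogger(__name__)

__all__ = ["CenteredMatrix", "center_by_control", "cluster", "HCAResult", "to_newick"]

_DISTANCES = ("correlation", "euclidean")
_LINKAGES = ("average", "complete", "single")


@dataclass
class CenteredMatrix:
    """Feature x sample deviations from the control mean."""

    values: pd.DataFrame  # features in rows, samples in columns
    control_label: str

    @property
    def features(self) -> pd.Index:
        return self.values.index


def center_by_control(
    table: NormalizedTable,
    control_label: str = "CK",
    condition_axis: str = "condition",
    log2: bool = False,
) -> CenteredMatrix:
    """Subtract each feature's mean over control samples.

    The result is oriented features x samples.  With ``log2`` the
    normalized ratios are log2-transformed before centering, making the
    deviations read as log2 fold changes versus control.
    """
    meta = table.metadata
    controls = meta.index[meta[condition_axis].astype(str) == str(control_label)]
    if len(controls) == 0:
        raise ValueError(f"no control samples with {condition_axis} == {control_label!r}")
    values = table.values
    if log2:
        if (values <= 0).any().any():
            raise ValueError("log2 transform requires strictly positive values")
        values = np.log2(values)
    centered = values.sub(values.loc[controls].mean(axis=0), axis=1)
    return CenteredMatrix(values=centered.T, control_label=str(control_label))


@dataclass
class HCAResult:
    matrix: pd.DataFrame          # centered, rows/cols in original order
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None  # None when only one column
    row_order: list
    col_order: list
    excluded_rows: tuple = ()

    def ordered_matrix(self) -> pd.DataFrame:
        return self.matrix.iloc[
            [self.matrix.index.get_loc(r) for r in self.row_order],
            [self.matrix.columns.get_loc(c) for c in self.col_order],
        ]


def _distance(values: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        return pdist(values, metric="correlation")  # 1 - Pearson r
    return pdist(values, metric="euclidean")


def cluster(
    matrix: CenteredMatrix | pd.DataFrame,
    distance: str = "correlation",
    method: str = "average",
) -> HCAResult:
    """Agglomerative clustering of rows and columns.

    Correlation distance (1 - Pearson r) is undefined for constant
    rows/columns; those are excluded with a warning.  Linkage merge
    order is deterministic (SciPy breaks ties by the smallest cluster
    indices).
    """
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}")
    if method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    values = matrix.values if isinstance(matrix, CenteredMatrix) else matrix
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")

    excluded: tuple = ()
    if distance == "correlation":
        row_sd = values.std(axis=1, ddof=0)
        bad = list(values.index[row_sd == 0])
        if bad:
            logger.warning("excluding %d constant row(s) under correlation distance: %s",
                           len(bad), bad)
            values = values.drop(index=bad)
            excluded = tuple(bad)
        col_sd = values.std(axis=0, ddof=0)
        bad_cols = list(values.columns[col_sd == 0])
        if bad_cols:
            logger.warning("excluding %d constant column(s): %s", len(bad_cols), bad_cols)
            values = values.drop(columns=bad_cols)

    row_z = linkage(_distance(values.to_numpy(dtype=float), distance), method=method)
    if values.shape[1] >= 2:
        col_z = linkage(_distance(values.to_numpy(dtype=float).T, distance),
                        method=method)
        col_order = [values.columns[i] for i in leaves_list(col_z)]
    else:
        col_z, col_order = None, list(values.columns)
    return HCAResult(
        matrix=values,
        row_linkage=row_z,
        col_linkage=col_z,
        row_order=[values.index[i] for i in leaves_list(row_z)],
        col_order=col_order,
        excluded_rows=excluded,
    )


def to_newick(linkage_matrix: np.ndarray, labels: list) -> str:
    """Render a SciPy linkage tree as a Newick string with branch lengths."""
    tree = to_tree(linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def write_hca(result: HCAResult, out_prefix: str | Path, delimiter: str = "\t") -> list[Path]:
    """Write the ordered matrix and both dendrograms; returns the paths."""
    prefix = Path(out_prefix)
    matrix_path = prefix.with_name(prefix.name + "matrix.tsv")
    rows_path = prefix.with_name(prefix.name + "rows.nwk")
    cols_path = prefix.with_name(prefix.name + "cols.nwk")
    result.ordered_matrix().to_csv(matrix_path, sep=delimiter)
    rows_path.write_text(to_newick(result.row_linkage, list(result.matrix.index)) + "\n")
    if result.col_linkage is not None:
        cols_path.write_text(
            to_newick(result.col_linkage, list(result.matrix.columns)) + "\n"
        )
    else:
        cols_path.write_text(f"{result.matrix.columns[0]};\n")
    return [matrix_path, rows_path, cols_path]
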