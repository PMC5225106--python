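"""Peak-table ingestion, validation, and internal-standard normalization.

A peak table is a samples x features matrix of GC-MS signal integration
areas together with per-sample design metadata (genotype, condition,
timepoint, replicate) and one designated internal-standard feature
(ribitol by default).  Normalization divides every feature area by the
sample's internal-standard area, correcting extraction and injection
variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "NormalizedTable",
    "read_peak_table",
    "read_metadata",
    "normalize_internal_standard",
    "handle_missing",
    "write_table",
]

REQUIRED_METADATA = ("genotype", "condition", "timepoint", "replicate")


@dataclass
class PeakTable:
    """Raw intensity matrix (samples in rows) plus design metadata."""

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    internal_standard: str = "ribitol"
    annotated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.intensities.index
        if idx.duplicated().any():
            raise ValueError(f"duplicate sample ids: {sorted(idx[idx.duplicated()])}")
        cols = self.intensities.columns
        if cols.duplicated().any():
            raise ValueError(f"duplicate feature ids: {sorted(cols[cols.duplicated()])}")
        if self.internal_standard not in cols:
            raise ValueError(
                f"internal standard {self.internal_standard!r} absent from features"
            )
        missing_meta = idx.difference(self.metadata.index)
        if len(missing_meta):
            raise ValueError(f"samples absent from metadata: {sorted(missing_meta)}")
        extra_meta = self.metadata.index.difference(idx)
        if len(extra_meta):
            raise ValueError(f"metadata samples absent from matrix: {sorted(extra_meta)}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata misses required column {col!r}")
        istd = self.intensities[self.internal_standard]
        bad = istd.index[~(istd > 0) | istd.isna()]
        if len(bad):
            raise ValueError(
                f"internal standard not strictly positive in samples: {sorted(bad)}"
            )
        # align metadata row order with the matrix
        self.metadata = self.metadata.loc[idx]

    @property
    def features(self) -> list[str]:
        return [c for c in self.intensities.columns if c != self.internal_standard]

    @property
    def n_missing(self) -> int:
        return int(self.intensities[self.features].isna().sum().sum())


@dataclass
class NormalizedTable:
    """Internal-standard-normalized ratios; the standard column is gone."""

    values: pd.DataFrame
    metadata: pd.DataFrame
    annotated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.metadata = self.metadata.loc[self.values.index]

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def groups(self, *axes: str):
        """Iterate (labels, sample-index) over metadata level combinations."""
        for labels, sub in self.metadata.groupby(list(axes), sort=False, observed=True):
            yield labels, sub.index


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".tab", ".txt"):
        return "\t"
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_metadata(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter))
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: metadata requires a sample_id column")
    return meta.set_index("sample_id")


def read_peak_table(
    path: str | Path,
    metadata_path: str | Path,
    internal_standard_name: str = "ribitol",
    delimiter: str | None = None,
) -> PeakTable:
    """Read a delimited peak table in either orientation.

    Orientation (samples in rows vs columns) is detected by matching the
    metadata sample identifiers against the file's row index and header;
    a transposed file yields the identical PeakTable.  Cells equal to
    NA/NaN/empty become missing values (counted and logged); any other
    non-numeric cell is an error naming its position.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    meta = read_metadata(metadata_path, delimiter)

    samples = set(meta.index)
    in_rows = len(samples & set(raw.index))
    in_cols = len(samples & set(raw.columns))
    if in_rows == 0 and in_cols == 0:
        raise ValueError(f"{path}: no metadata sample ids found in rows or columns")
    if in_cols > in_rows:
        raw = raw.T
    raw.index.name = "sample_id"
    raw.columns.name = None

    # read_csv maps NA/NaN/empty tokens to NaN already, so any cell that
    # survives reading but fails numeric coercion is a genuine parse error
    matrix = raw.apply(pd.to_numeric, errors="coerce")
    bad = matrix.isna() & raw.notna()
    non_numeric = list(zip(*np.where(bad)))
    if non_numeric:
        r, c = non_numeric[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {matrix.index[r]!r}, "
            f"column {matrix.columns[c]!r} (value {raw.iat[r, c]!r}); "
            f"{len(non_numeric)} offending cell(s) total"
        )
    n_missing = int(matrix.isna().sum().sum())
    if n_missing:
        logger.info("%s: %d missing cell(s)", path, n_missing)

    return PeakTable(
        intensities=matrix,
        metadata=meta,
        internal_standard=internal_standard_name,
    )


def normalize_internal_standard(table: PeakTable) -> NormalizedTable:
    """Divide every feature area by the sample's internal-standard area.

    The internal-standard column is removed from the output; missing
    inputs stay missing.
    """
    istd = table.intensities[table.internal_standard]
    bad = istd.index[~(istd > 0) | istd.isna()]
    if len(bad):
        raise ValueError(
            f"zero or missing internal standard in samples: {sorted(bad)}"
        )
    values = table.intensities[table.features].div(istd, axis=0)
    return NormalizedTable(
        values=values, metadata=table.metadata.copy(), annotated=table.annotated
    )


def handle_missing(
    table: NormalizedTable,
    policy: str = "default",
    drop_rate: float = 0.3,
) -> NormalizedTable:
    """Resolve missing values in a normalized table.

    Policies: ``drop_feature_above_rate`` removes features missing in
    more than ``drop_rate`` of samples (remaining gaps stay);
    ``impute_half_min`` fills gaps with half the feature's observed
    minimum; ``fail`` raises on any missing value; ``default`` drops
    above the rate then imputes the rest — mirroring the common
    min-fraction filtering convention for GC-MS peak groups.
    """
    if not 0.0 <= drop_rate <= 1.0:
        raise ValueError("drop_rate must lie in [0, 1]")
    values = table.values
    miss = values.isna()
    if policy == "fail":
        if miss.any().any():
            cols = sorted(values.columns[miss.any()])
            raise ValueError(f"missing values present in features: {cols}")
        return table

    out = values
    if policy in ("default", "drop_feature_above_rate"):
        rate = miss.mean(axis=0)
        dropped = list(values.columns[rate > drop_rate])
        if dropped:
            logger.info("dropping %d feature(s) above missing rate %.2f: %s",
                        len(dropped), drop_rate, dropped)
        out = values.drop(columns=dropped)
    if policy in ("default", "impute_half_min"):
        still = out.isna()
        if still.any().any():
            fills = out.min(axis=0, skipna=True) / 2.0
            for col in out.columns[still.any()]:
                logger.info("imputing %d cell(s) of %r with half-min %.4g",
                            int(still[col].sum()), col, fills[col])
            out = out.fillna(fills)
    if policy not in ("default", "drop_feature_above_rate", "impute_half_min"):
        raise ValueError(f"unknown missing-value policy {policy!r}")
    annotated = tuple(a for a in table.annotated if a in out.columns)
    return NormalizedTable(values=out, metadata=table.metadata.copy(), annotated=annotated)


def write_table(
    frame: pd.DataFrame, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a frame as delimited text with the index as first column."""
    frame.to_csv(path, sep=delimiter)


def write_peak_table(table: PeakTable, path: str | Path, metadata_path: str | Path,
                     delimiter: str = "\t") -> None:
    write_table(table.intensities, path, delimiter)
    write_table(table.metadata, metadata_path, delimiter)
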