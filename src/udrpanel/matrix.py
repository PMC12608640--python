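"""Expression matrices and their on-disk format.

The whole pipeline operates on a single container, :class:`ExpressionMatrix`:
a feature-by-sample numeric table tagged with the scale its values live on.
Four scales occur in practice:

``counts``
    raw NGS read counts (non-negative integers),
``ct``
    raw qPCR cycle-threshold values (lower = more abundant),
``delta_ct``
    spike-in-normalized qPCR abundance, Ct(spike) - Ct(miRNA); one cycle
    is one doubling, so this is a log2-scale abundance,
``linear``
    strictly positive relative expression (CPM + pseudocount, or 2**delta_ct).

Files are plain tab-separated text: first column feature IDs, header row
sample IDs, empty cells (or ``-``, the convention for undetermined qPCR
reactions) for missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("counts", "ct", "delta_ct", "linear")

#: tokens interpreted as a missing measurement when reading expression files
MISSING_TOKENS = ("", "-", "NA", "NaN", "nan")


class ExpressionError(ValueError):
    """Malformed expression data (bad file, bad values, scale violation)."""


@dataclass
class ExpressionMatrix:
    """A feature-by-sample numeric matrix with a declared measurement scale.

    Parameters
    ----------
    data:
        DataFrame with feature IDs as the index and sample IDs as columns.
        ``NaN`` encodes a missing measurement.
    scale:
        One of :data:`SCALES`.
    """

    data: pd.DataFrame
    scale: str = field(default="counts")

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ExpressionError(
                f"unknown scale {self.scale!r}; expected one of {SCALES}"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate feature IDs: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate sample IDs: {dupes}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        finite = vals[np.isfinite(vals)]
        if self.scale == "counts":
            if finite.size and (np.any(finite < 0) or np.any(finite != np.round(finite))):
                raise ExpressionError(
                    "scale='counts' requires non-negative integer values"
                )
        elif self.scale == "linear":
            if finite.size and np.any(finite <= 0):
                raise ExpressionError("scale='linear' requires strictly positive values")

    # -- basic accessors ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)].copy(), self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)].copy(), self.scale)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.scale == other.scale
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def read_expression(path, scale: str) -> ExpressionMatrix:
    """Read a tab-separated expression table.

    First column holds feature IDs, the header row holds sample IDs.  Empty
    cells and ``-`` parse as missing.  Duplicated feature IDs, non-numeric
    cells and (for ``scale='counts'``) fractional or negative values are
    rejected.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    if df.index.name is None and df.index.has_duplicates is False and df.shape[1] == 0:
        # header-only file with zero features: still valid
        pass
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ExpressionError(f"duplicate feature IDs in {path}: {dupes}")
    parsed = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        is_missing = raw.isin(MISSING_TOKENS)
        numeric = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = (~is_missing) & numeric.isna()
        if bad.any():
            feat = df.index[bad][0]
            raise ExpressionError(
                f"non-numeric cell {raw[bad].iloc[0]!r} at feature {feat!r}, sample {col!r}"
            )
        parsed[col] = numeric
    return ExpressionMatrix(parsed, scale)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as tab-separated text; inverse of :func:`read_expression`.

    Missing values are written as empty cells.  Floats are written with
    ``repr`` precision so that a read/write round trip is exact.
    """
    df = matrix.data.copy()
    # keep integer formatting for count matrices so round trips are byte-stable
    if matrix.scale == "counts" and not df.isna().any().any():
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", na_rep="", index_label="feature_id")
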