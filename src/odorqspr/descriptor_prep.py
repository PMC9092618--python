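"""Descriptor-matrix pre-filtering, spline terms, and autoscaling.

The raw descriptor pool (any numeric compounds x descriptors matrix) is
cleaned before modeling: columns with missing values, (near-)constant
columns (SD < 1e-4), and the later member of any pair with |Pearson r|
>= 0.95 are dropped.  Truncated-spline basis terms <a - x> = max(0, a - x)
and unit-variance autoscaling are shared primitives for all later stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "SplineTerm",
    "prefilter",
    "spline_value",
    "autoscale",
    "Scaler",
]

#: minimum column standard deviation (n-1 denominator) to count as informative
SD_MIN_DEFAULT = 0.0001
#: absolute pairwise Pearson correlation at or above which the later column is dropped
R_MAX_DEFAULT = 0.95


class DescriptorError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors with filtering provenance.

    ``data`` is a DataFrame indexed by compound id with numeric columns.
    ``removed_columns`` records (name, reason) pairs accumulated by
    :func:`prefilter`.
    """

    data: pd.DataFrame
    removed_columns: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DescriptorError("duplicate compound ids in descriptor matrix")
        if self.data.columns.has_duplicates:
            raise DescriptorError("duplicate descriptor names")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(data=df.astype(float))

    def removal_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_columns, columns=["name", "reason"])


@dataclass(frozen=True)
class SplineTerm:
    """Truncated linear basis <knot - descriptor>, zero where negative."""

    descriptor: str
    knot: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.knot):
            raise DescriptorError(f"spline knot for {self.descriptor!r} must be finite")

    @property
    def label(self) -> str:
        return f"<{self.knot:g}-{self.descriptor}>"


def spline_value(term: SplineTerm, x):
    """Evaluate max(0, knot - x); accepts scalars or arrays."""
    return np.maximum(0.0, term.knot - np.asarray(x, dtype=float))


def prefilter(X: DescriptorMatrix, sd_min: float = SD_MIN_DEFAULT,
              r_max: float = R_MAX_DEFAULT) -> DescriptorMatrix:
    """Drop uninformative and redundant descriptor columns.

    Removal happens in three ordered passes, each logged with a reason:

    1. columns with any missing value (includes all-missing columns);
    2. columns with standard deviation (n-1 denominator) below ``sd_min``;
    3. for every pair with |Pearson r| >= ``r_max``, the column listed
       later in file order (the earlier column is kept).

    The operation is idempotent: a matrix already satisfying all three
    rules is returned unchanged.
    """
    df = X.data
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise DescriptorError("empty descriptor matrix")
    if df.shape[0] < 3:
        raise DescriptorError("need at least 3 compounds to prefilter")

    removed: list[tuple[str, str]] = list(X.removed_columns)

    has_missing = df.isna().any(axis=0)
    for name in df.columns[has_missing]:
        removed.append((name, "missing values"))
    df = df.loc[:, ~has_missing]

    sds = df.std(axis=0, ddof=1)
    low_sd = sds < sd_min
    for name in df.columns[low_sd]:
        removed.append((name, f"sd<{sd_min:g}"))
    df = df.loc[:, ~low_sd]

    if df.shape[1] > 0:
        corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
        corr = np.atleast_2d(corr)
        cols = list(df.columns)
        keep = np.ones(len(cols), dtype=bool)
        for j in range(len(cols)):
            if not keep[j]:
                continue
            for k in range(j + 1, len(cols)):
                if keep[k] and abs(corr[j, k]) >= r_max:
                    keep[k] = False
                    removed.append((cols[k], f"|r|>={r_max:g} with {cols[j]}"))
        df = df.loc[:, keep]

    if df.shape[1] == 0:
        import warnings

        warnings.warn("prefilter removed every descriptor column", stacklevel=2)
    return DescriptorMatrix(data=df.copy(), removed_columns=removed)


@dataclass
class Scaler:
    """Column means and SDs (n-1 denominator) fitted on training data."""

    means: pd.Series
    sds: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.means.index] - self.means) / self.sds

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        return df[self.means.index] * self.sds + self.means


def autoscale(X: DescriptorMatrix | pd.DataFrame) -> tuple[pd.DataFrame, Scaler]:
    """Center to mean 0 and scale to unit SD (n-1 denominator) per column.

    Returns the scaled frame and the fitted :class:`Scaler` so the same
    transformation can be applied to new compounds.  A zero-SD column is
    an error (such columns should have been removed by prefilter).
    """
    df = X.data if isinstance(X, DescriptorMatrix) else X
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise DescriptorError(f"zero-SD columns cannot be autoscaled: {list(zero.index)}")
    scaler = Scaler(means=means, sds=sds)
    return scaler.transform(df), scaler
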