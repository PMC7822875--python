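"""Trait and expression preprocessing.

Traits are rank-inverse-normal transformed (Blom offset) and standardized to
mean 0 / SD 1 before any mixed-model analysis; expression counts are scaled
to counts per million per sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rank_inverse_normal", "cpm_normalize"]


def rank_inverse_normal(
    values: np.ndarray | pd.Series, offset: float = 3.0 / 8.0
) -> np.ndarray:
    """Rank-based inverse normal transform, then center/scale to mean 0, SD 1.

    Each non-missing value is mapped to the standard-normal quantile of
    ``(rank - offset) / (n + 1 - 2*offset)`` with ties receiving their
    average rank (Blom scores for the default offset 3/8, where the
    denominator is ``n + 1/4``).  Missing values (NaN) are preserved.  The
    transform is monotone and invariant to any monotone pre-transform of the
    input.

    Raises ``ValueError`` for fewer than 3 non-missing values or if all
    non-missing values are identical (the transform is undefined).
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    x = arr[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 non-missing values, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("all values identical: rank transform undefined")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    z = (z - z.mean()) / z.std()
    out[mask] = z
    return out


def cpm_normalize(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Scale each sample (column) of a count matrix to sum to one million.

    Counts must be nonnegative; an all-zero sample column is an error and is
    reported by name (or column index for plain arrays).
    """
    is_frame = isinstance(counts, pd.DataFrame)
    mat = counts.to_numpy(dtype=float) if is_frame else np.asarray(counts, dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    colsums = mat.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        name = counts.columns[zero[0]] if is_frame else int(zero[0])
        raise ValueError(f"sample {name!r} has zero total counts; cannot CPM-normalize")
    cpm = mat / colsums * 1e6
    if is_frame:
        return pd.DataFrame(cpm, index=counts.index, columns=counts.columns)
    return cpm
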