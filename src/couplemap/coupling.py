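"""Node-wise structure-function coupling and class-level statistics.

Coupling at parcel i is the Spearman rank correlation between row i of the MPC
matrix and row i of the rsFC matrix, excluding the diagonal entry. The same
row-wise statistic applied to a mean-connectivity matrix and an edge-wise
heritability matrix gives the genetic coupling map.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CLASSES, ParcelAtlas
from .connectomes import ConnectivityMatrix

__all__ = ["rowwise_coupling", "genetic_coupling", "class_summary", "class_contrast"]


def _as_values(m) -> np.ndarray:
    if isinstance(m, ConnectivityMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def rowwise_coupling(a, b) -> np.ndarray:
    """Per-parcel Spearman correlation of matching rows of two matrices.

    The diagonal entry is excluded from each row. Constant rows yield NaN for
    that parcel (with a warning) rather than a spurious value.
    """
    A, B = _as_values(a), _as_values(b)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square with identical shape")
    if isinstance(a, ConnectivityMatrix) and isinstance(b, ConnectivityMatrix):
        if not np.array_equal(a.parcel_ids, b.parcel_ids):
            raise ValueError("matrices have mismatched parcel order")
    n = A.shape[0]
    out = np.empty(n)
    for i in range(n):
        ra = np.delete(A[i], i)
        rb = np.delete(B[i], i)
        if np.all(ra == ra[0]) or np.all(rb == rb[0]):
            warnings.warn(f"constant row at parcel {i}; coupling set to NaN",
                          RuntimeWarning, stacklevel=2)
            out[i] = np.nan
            continue
        out[i] = stats.spearmanr(ra, rb).statistic
    return out


def genetic_coupling(mean_matrix, h2_matrix) -> np.ndarray:
    """Per-parcel Spearman correlation of mean connectivity rows with h2 rows."""
    return rowwise_coupling(mean_matrix, h2_matrix)


def class_summary(parcel_map, atlas: ParcelAtlas) -> pd.DataFrame:
    """Mean and SD (ddof=1) of a parcel map within each cytoarchitectural class.

    Missing (NaN) parcels are dropped; an empty class is an error.
    """
    values = np.asarray(parcel_map, dtype=float)
    if values.size != atlas.n_parcels:
        raise ValueError("map length must equal atlas size")
    rows = []
    for cls in CLASSES:
        idx = atlas.class_indices(cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} is empty")
        v = values[idx]
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(f"class {cls!r} has no finite values")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        rows.append((cls, float(np.mean(v)), sd, v.size))
    return pd.DataFrame(rows, columns=["class", "mean", "sd", "n"]).set_index("class")


def class_contrast(
    parcel_map, atlas: ParcelAtlas, class_a: str, class_b: str,
    n_comparisons: int = 4,
) -> tuple[float, float]:
    """Welch two-sample t-test between two classes, Bonferroni-corrected.

    The p-value is multiplied by ``n_comparisons`` (the number of classes, by
    the reporting convention used for class-wise contrasts) and capped at 1.
    """
    values = np.asarray(parcel_map, dtype=float)
    va = values[atlas.class_indices(class_a)]
    vb = values[atlas.class_indices(class_b)]
    va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
    if va.size < 2 or vb.size < 2:
        raise ValueError("each class needs at least 2 finite values")
    res = stats.ttest_ind(va, vb, equal_var=False)
    t = float(res.statistic)
    p = min(1.0, float(res.pvalue) * n_comparisons)
    return t, p
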