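"""The 2D coordinate system of cortical organization and its decoding.

The x-axis is the gradient difference (Delta) map and the y-axis the
structure-function coupling map. Parcels are assigned to quadrants of the
z-standardized plane; quadrant occupancy can be compared across groups with a
Pearson chi-square, and external term-score maps are projected onto either axis
by 20-bin weighted-average ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_quadrants",
    "quadrant_counts",
    "quadrant_chisq",
    "binned_term_ranking",
    "QuadrantAssignment",
    "TermProjection",
]

QUADRANTS = ("UL", "UR", "LL", "LR")


@dataclass
class QuadrantAssignment:
    """Per-parcel quadrant labels on the (x = Delta, y = coupling) plane."""

    quadrant: np.ndarray  # of str, "" for missing parcels
    x0: float
    y0: float

    def counts(self) -> np.ndarray:
        """Counts in canonical order (UL, UR, LL, LR) over non-missing parcels."""
        return np.array([np.sum(self.quadrant == q) for q in QUADRANTS])


def assign_quadrants(x_map, y_map, x0: float = 0.0, y0: float = 0.0) -> QuadrantAssignment:
    """Assign parcels to quadrants of the z-standardized (x, y) plane.

    Upper means y > y0, left means x < x0 (after z-standardization of each
    axis). Parcels missing on either axis stay unassigned.
    """
    x = np.asarray(x_map, dtype=float)
    y = np.asarray(y_map, dtype=float)
    if x.size != y.size:
        raise ValueError("maps must share parcels")
    ok = np.isfinite(x) & np.isfinite(y)
    if x[ok].std() == 0 or y[ok].std() == 0:
        raise ValueError("zero-variance map cannot be quadrant-split")
    zx = np.full_like(x, np.nan)
    zy = np.full_like(y, np.nan)
    zx[ok] = (x[ok] - x[ok].mean()) / x[ok].std()
    zy[ok] = (y[ok] - y[ok].mean()) / y[ok].std()
    quad = np.full(x.size, "", dtype=object)
    upper = zy > y0
    left = zx < x0
    quad[ok & upper & left] = "UL"
    quad[ok & upper & ~left] = "UR"
    quad[ok & ~upper & left] = "LL"
    quad[ok & ~upper & ~left] = "LR"
    return QuadrantAssignment(quadrant=quad.astype(str), x0=x0, y0=y0)


def quadrant_counts(assignment: QuadrantAssignment) -> np.ndarray:
    return assignment.counts()


def quadrant_chisq(counts_group1, counts_group2) -> tuple[float, float]:
    """Pearson chi-square comparing quadrant occupancy between two groups.

    The 2 x k contingency table is tested with df = k - 1 (no continuity
    correction). An expected cell of zero is an error.
    """
    c1 = np.asarray(counts_group1, dtype=float)
    c2 = np.asarray(counts_group2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1:
        raise ValueError("count vectors must be 1-D with the same length")
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("counts must be non-negative")
    table = np.vstack([c1, c2])
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    expected = np.outer(row, col) / table.sum()
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero")
    chi2 = float(np.sum((table - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=c1.size - 1))
    return chi2, p


@dataclass
class TermProjection:
    """Weighted-average positions and ranks of terms along one axis."""

    terms: list
    position: np.ndarray  # weighted mean bin position per term (NaN if missing)
    rank: np.ndarray  # 1 = largest position; NaN for missing terms
    bin_means: np.ndarray  # (n_terms, n_bins)
    shifted: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.position, "rank": self.rank},
                            index=pd.Index(self.terms, name="term"))


def binned_term_ranking(
    term_maps, axis_map, n_bins: int = 20, terms=None, shift_nonnegative: bool = True
) -> TermProjection:
    """Rank term-score maps along an axis by 20-bin weighted averaging.

    Parcels are sorted by the axis map and split into ``n_bins`` near-equal
    bins (sizes differ by at most 1; ties in the axis broken by parcel index).
    Per term, the mean score per bin is computed; the weighted mean position is
    sum(bin_index * weight) / sum(weight) with bin indices 1..n_bins. By
    default the weights are the bin means shifted to be non-negative (their
    per-term minimum subtracted), since a weighted average over signed z-scores
    is ill-defined; ``shift_nonnegative=False`` uses the raw bin means.

    Terms whose weights are all zero get a missing position/rank. Rank 1 is the
    largest position; rank ties are broken by term name.
    """
    T = np.asarray(term_maps, dtype=float)
    axis = np.asarray(axis_map, dtype=float)
    if T.ndim != 2 or T.shape[0] != axis.size:
        raise ValueError("term_maps must be (n_parcels, n_terms) matching the axis map")
    n_parcels, n_terms = T.shape
    if terms is None:
        terms = [f"term_{j}" for j in range(n_terms)]
    terms = [str(t) for t in terms]
    if n_bins < 2 or n_bins > n_parcels:
        raise ValueError("n_bins must lie in [2, n_parcels]")
    order = np.lexsort((np.arange(n_parcels), axis))  # ties by parcel index
    bins = np.array_split(order, n_bins)
    bin_means = np.vstack([T[b].mean(axis=0) for b in bins]).T  # (terms, bins)
    idx = np.arange(1, n_bins + 1, dtype=float)
    position = np.full(n_terms, np.nan)
    for j in range(n_terms):
        w = bin_means[j]
        if shift_nonnegative:
            w = w - w.min()
        total = w.sum()
        if total <= 0:
            continue  # flagged missing
        position[j] = float((idx * w).sum() / total)
    rank = np.full(n_terms, np.nan)
    ok = np.flatnonzero(np.isfinite(position))
    # sort by descending position, ties by term name
    ok_sorted = sorted(ok, key=lambda j: (-position[j], terms[j]))
    for r, j in enumerate(ok_sorted, start=1):
        rank[j] = r
    return TermProjection(terms=terms, position=position, rank=rank,
                          bin_means=bin_means, shifted=shift_nonnegative)
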