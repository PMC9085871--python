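"""Spin-test permutation nulls for correlations between parcel maps.

The null preserves spatial autocorrelation: parcel centroids are rotated on the
sphere by a uniform random rotation (mirrored across the midline for the right
hemisphere) and each rotated parcel is reassigned to the nearest original
centroid within its hemisphere, one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .atlas import ParcelAtlas

__all__ = ["spin_permute", "spin_test_correlation", "SpinNull"]


@dataclass
class SpinNull:
    """Observed statistic, spin-null distribution, and the permutation p-value."""

    observed: float
    null: np.ndarray
    p_spin: float
    n_perm: int
    seed: int


def _greedy_match(cost: np.ndarray) -> np.ndarray:
    """One-to-one assignment, nearest pairs first.

    Returns ``assign`` with assign[original_slot] = rotated parcel index.
    """
    n = cost.shape[0]
    order = np.argsort(cost, axis=None, kind="stable")
    assign = np.full(n, -1, dtype=int)
    row_used = np.zeros(n, dtype=bool)
    col_used = np.zeros(n, dtype=bool)
    filled = 0
    for flat in order:
        i, j = divmod(int(flat), n)
        if row_used[i] or col_used[j]:
            continue
        assign[i] = j
        row_used[i] = col_used[j] = True
        filled += 1
        if filled == n:
            break
    return assign


def spin_permute(atlas: ParcelAtlas, n_perm: int, seed: int) -> np.ndarray:
    """Spin permutation table of shape (n_perm, n_parcels).

    Row t gives the permutation pi_t: the null map at parcel i is
    ``map[pi_t[i]]``. The left hemisphere gets a uniform random rotation R; the
    right hemisphere gets its x-mirrored counterpart F R F, keeping the two
    hemispheres' spins mirror-symmetric.
    """
    left = atlas.hemisphere_indices("L")
    right = atlas.hemisphere_indices("R")
    if left.size < 3 or right.size < 3:
        raise ValueError("need at least 3 parcels per hemisphere")
    rng = np.random.default_rng(seed)
    F = np.diag([-1.0, 1.0, 1.0])
    table = np.empty((n_perm, atlas.n_parcels), dtype=int)
    for t in range(n_perm):
        R = stats.special_ortho_group.rvs(3, random_state=rng)
        for idx, rot in ((left, R), (right, F @ R @ F)):
            pts = atlas.centroids[idx]
            rotated = pts @ rot.T
            # cost[i, j] = distance from original centroid i to rotated parcel j
            cost = np.linalg.norm(pts[:, None, :] - rotated[None, :, :], axis=2)
            assign = _greedy_match(cost)
            table[t, idx] = idx[assign]
    return table


def spin_test_correlation(
    map_a,
    map_b,
    atlas: ParcelAtlas,
    n_perm: int = 1000,
    seed: int = 0,
    table: np.ndarray | None = None,
) -> SpinNull:
    """Two-sided spin test of the Spearman correlation between two parcel maps.

    ``map_a`` is the map that gets rotated. The p-value uses the +1 convention:
    p = (1 + #{|null| >= |observed|}) / (1 + n_perm).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != atlas.n_parcels or b.size != atlas.n_parcels:
        raise ValueError("maps must match the atlas size")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant map; correlation undefined")
    observed = float(stats.spearmanr(a, b).statistic)
    if table is None:
        table = spin_permute(atlas, n_perm, seed)
    else:
        n_perm = table.shape[0]
    null = np.array([stats.spearmanr(a[perm], b).statistic for perm in table])
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return SpinNull(observed=observed, null=null, p_spin=float(p),
                    n_perm=n_perm, seed=seed)
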