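"""Equivolumetric depth sampling of intracortical intensity profiles.

On a folded cortex, surfaces placed at fixed Euclidean depth fractions
over-sample deep laminae on gyri and superficial laminae in sulci. The
equivolumetric model instead places each intracortical surface so that a fixed
fraction ``alpha`` of the local cortical volume lies on one side of it.
Interpolating the local surface area linearly between a vertex's inner (white)
area ``A_in`` and outer (pial) area ``A_out`` across the cortical ribbon gives
the closed-form depth fraction

    rho(alpha) = (-A_in + sqrt(alpha * A_out**2 + (1 - alpha) * A_in**2))
                 / (A_out - A_in)

with the equal-area limit rho = alpha. In the formula's own orientation the
depth coordinate runs from the A_in side (rho = 0) to the A_out side (rho = 1)
and alpha is the volume fraction between the A_in boundary and the surface;
because the default fraction grid k/(n+1) is symmetric, the orientation
convention does not affect which set of surfaces is produced.
"""

from __future__ import annotations

import numpy as np

from .atlas import ParcelAtlas

__all__ = [
    "equivolumetric_fraction",
    "make_fraction_grid",
    "sample_profiles",
    "parcel_mean_profiles",
    "ParcelProfileMatrix",
]

#: relative area difference below which the removable singularity is replaced
#: by its analytic limit rho = alpha
_EQUAL_AREA_RTOL = 1e-9


def equivolumetric_fraction(area_inner, area_outer, alpha):
    """Euclidean depth fraction of the surface enclosing volume fraction ``alpha``.

    Parameters
    ----------
    area_inner, area_outer : float or array
        Local inner (white) and outer (pial) surface areas; strictly positive.
    alpha : float or array
        Volume fraction in [0, 1], measured from the ``area_inner`` boundary.

    Returns
    -------
    rho : float or array
        Depth fraction in [0, 1]; 0 is the ``area_inner`` boundary, 1 the
        ``area_outer`` boundary (see module docstring on orientation).
    """
    a_in = np.asarray(area_inner, dtype=float)
    a_out = np.asarray(area_outer, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(a_in <= 0) or np.any(a_out <= 0):
        raise ValueError("surface areas must be strictly positive")
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    a_in, a_out, alpha = np.broadcast_arrays(a_in, a_out, alpha)
    diff = a_out - a_in
    near_equal = np.abs(diff) < _EQUAL_AREA_RTOL * np.abs(a_in)
    safe_diff = np.where(near_equal, 1.0, diff)
    rho = (-a_in + np.sqrt(alpha * a_out**2 + (1.0 - alpha) * a_in**2)) / safe_diff
    rho = np.where(near_equal, alpha, rho)
    if rho.ndim == 0:
        return float(rho)
    return rho


def make_fraction_grid(n_surfaces: int) -> np.ndarray:
    """Volume fractions alpha_k = k/(n+1), k = 1..n, for n intracortical surfaces.

    Surfaces lie strictly between the pial and white boundaries (0 and 1 are
    excluded), so no sample sits in a boundary partial-volume zone.
    """
    if n_surfaces < 2:
        raise ValueError("need at least 2 surfaces")
    k = np.arange(1, n_surfaces + 1, dtype=float)
    return k / (n_surfaces + 1)


def sample_profiles(intensity, fractions, *, depths=None) -> np.ndarray:
    """Sample per-vertex intensities at the given depth fractions.

    Parameters
    ----------
    intensity : callable or (n_vertices, n_tab) array
        Either a vectorized callable ``intensity(rho)`` mapping an
        (n_vertices, n_surfaces) array of depth fractions to intensities, or a
        table of intensities at tabulated depths (linear interpolation).
    fractions : (n_surfaces,) or (n_vertices, n_surfaces) array
        Depth fractions in [0, 1]; index 0 is the surface nearest the outer
        (pial) boundary.
    depths : (n_tab,) array, optional
        Tabulated depths for the array form of ``intensity``; defaults to a
        uniform grid on [0, 1].

    Returns
    -------
    (n_vertices, n_surfaces) array
    """
    fractions = np.asarray(fractions, dtype=float)
    if callable(intensity):
        return np.asarray(intensity(fractions), dtype=float)
    table = np.asarray(intensity, dtype=float)
    if table.ndim != 2:
        raise ValueError("intensity table must be 2-D (vertices x tabulated depths)")
    if depths is None:
        depths = np.linspace(0.0, 1.0, table.shape[1])
    depths = np.asarray(depths, dtype=float)
    if np.any(fractions < depths[0]) or np.any(fractions > depths[-1]):
        raise ValueError("requested fraction outside the tabulated depth range")
    if fractions.ndim == 1:
        fractions = np.broadcast_to(fractions, (table.shape[0], fractions.size))
    out = np.empty(fractions.shape, dtype=float)
    for v in range(table.shape[0]):
        out[v] = np.interp(fractions[v], depths, table[v])
    return out


class ParcelProfileMatrix:
    """Mean depth profile per parcel for one subject.

    Attributes
    ----------
    profiles : (n_parcels, n_depths) array
        Unweighted mean intensity over each parcel's unmasked vertices.
    mean_profile : (n_depths,) array
        Cortex-wide profile ``c``: the unweighted mean over parcels.
    parcel_ids : array of str
    """

    def __init__(self, profiles, parcel_ids=None, subject=None):
        self.profiles = np.asarray(profiles, dtype=float)
        if self.profiles.ndim != 2:
            raise ValueError("profiles must be 2-D (parcels x depths)")
        if not np.all(np.isfinite(self.profiles)):
            raise ValueError("profiles must be finite")
        n = self.profiles.shape[0]
        if parcel_ids is None:
            parcel_ids = np.array([f"parcel_{i:04d}" for i in range(n)])
        self.parcel_ids = np.asarray(parcel_ids, dtype=str)
        if self.parcel_ids.size != n:
            raise ValueError("parcel_ids length mismatch")
        self.subject = subject

    @property
    def n_parcels(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_depths(self) -> int:
        return self.profiles.shape[1]

    @property
    def mean_profile(self) -> np.ndarray:
        return self.profiles.mean(axis=0)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.profiles, index=self.parcel_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, subject=None) -> "ParcelProfileMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), parcel_ids=df.index.to_numpy(), subject=subject)


def parcel_mean_profiles(
    vertex_profiles,
    vertex_parcel,
    atlas: ParcelAtlas | None = None,
    mask=None,
    subject=None,
) -> ParcelProfileMatrix:
    """Average vertex-wise depth profiles into parcel profiles.

    Parameters
    ----------
    vertex_profiles : (n_vertices, n_depths) array
    vertex_parcel : (n_vertices,) int array
        Parcel index per vertex.
    atlas : ParcelAtlas, optional
        Supplies the parcel count and ids; otherwise inferred from labels.
    mask : (n_vertices,) bool array, optional
        True marks vertices to keep.
    """
    vertex_profiles = np.asarray(vertex_profiles, dtype=float)
    vertex_parcel = np.asarray(vertex_parcel, dtype=int)
    if mask is None:
        mask = np.ones(vertex_parcel.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_parcels = atlas.n_parcels if atlas is not None else vertex_parcel.max() + 1
    parcel_ids = atlas.parcel_ids if atlas is not None else None
    n_depths = vertex_profiles.shape[1]
    out = np.empty((n_parcels, n_depths), dtype=float)
    for p in range(n_parcels):
        sel = mask & (vertex_parcel == p)
        if not np.any(sel):
            name = parcel_ids[p] if parcel_ids is not None else str(p)
            raise ValueError(f"parcel {name} has no unmasked vertices")
        out[p] = vertex_profiles[sel].mean(axis=0)
    return ParcelProfileMatrix(out, parcel_ids=parcel_ids, subject=subject)
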