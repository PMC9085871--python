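"""Parcel atlas: class labels, spherical centroids, and the canonical parcel order.

Every matrix and map in the pipeline is indexed by the parcel order defined here.
Classes follow the sensory-fugal cytoarchitectural taxonomy: idiotypic (primary
sensory/motor), unimodal association, heteromodal association, and paralimbic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical cytoarchitectural class order, from primary to paralimbic cortex.
CLASSES = ("idiotypic", "unimodal", "heteromodal", "paralimbic")


@dataclass
class ParcelAtlas:
    """Shared parcel bookkeeping for all pipeline stages.

    Parameters
    ----------
    parcel_ids : array of str
        Ordered parcel identifiers; this order is canonical for every matrix.
    class_labels : array of str
        One of :data:`CLASSES` per parcel.
    centroids : (n_parcels, 3) array
        Unit-sphere centroid per parcel (used by the spin test).
    hemispheres : array of str
        'L' or 'R' per parcel.
    """

    parcel_ids: np.ndarray
    class_labels: np.ndarray
    centroids: np.ndarray
    hemispheres: np.ndarray

    def __post_init__(self) -> None:
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=str)
        self.class_labels = np.asarray(self.class_labels, dtype=str)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.hemispheres = np.asarray(self.hemispheres, dtype=str)
        n = self.parcel_ids.size
        if not (self.class_labels.size == n and self.hemispheres.size == n
                and self.centroids.shape == (n, 3)):
            raise ValueError("atlas field lengths disagree")
        bad = set(self.class_labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must have unit norm")
        if not set(self.hemispheres) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")

    @property
    def n_parcels(self) -> int:
        return self.parcel_ids.size

    def class_indices(self, label: str) -> np.ndarray:
        """Indices of parcels belonging to one cytoarchitectural class."""
        if label not in CLASSES:
            raise ValueError(f"unknown class {label!r}")
        return np.flatnonzero(self.class_labels == label)

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemispheres == hemi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "class": self.class_labels,
                "hemi": self.hemispheres,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParcelAtlas":
        df = pd.read_csv(path, dtype={"parcel_id": str})
        return cls(
            parcel_ids=df["parcel_id"].to_numpy(),
            class_labels=df["class"].to_numpy(),
            centroids=df[["x", "y", "z"]].to_numpy(),
            hemispheres=df["hemi"].to_numpy(),
        )


@dataclass
class ToyCortex:
    """A synthetic cortex: an atlas plus per-vertex parcel labels and local areas.

    ``area_inner``/``area_outer`` are the local inner (white) and outer (pial)
    surface areas attached to each vertex; the equivolumetric depth formula needs
    only these two scalars per vertex.
    """

    atlas: ParcelAtlas
    vertex_parcel: np.ndarray  # (n_vertices,) int parcel index
    area_inner: np.ndarray  # (n_vertices,) > 0
    area_outer: np.ndarray  # (n_vertices,) > 0

    def __post_init__(self) -> None:
        self.vertex_parcel = np.asarray(self.vertex_parcel, dtype=int)
        self.area_inner = np.asarray(self.area_inner, dtype=float)
        self.area_outer = np.asarray(self.area_outer, dtype=float)
        if np.any(self.area_inner <= 0) or np.any(self.area_outer <= 0):
            raise ValueError("vertex areas must be strictly positive")
        if self.vertex_parcel.min() < 0 or self.vertex_parcel.max() >= self.atlas.n_parcels:
            raise ValueError("vertex parcel labels out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertex_parcel.size


def fibonacci_sphere(n: int) -> np.ndarray:
    """Spread ``n`` points quasi-uniformly over the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_toy_cortex(
    n_parcels: int,
    seed: int,
    vertices_per_parcel: int = 10,
) -> ToyCortex:
    """Construct a deterministic toy cortex for simulation and testing.

    Each hemisphere is represented on its own unit sphere, as in standard
    surface atlases: left-hemisphere centroids come from a Fibonacci lattice
    and right-hemisphere centroids are its x-mirrored copy, so homotopic parcel
    pairs sit at mirrored positions. The four cytoarchitectural classes are
    assigned as contiguous latitude bands (one quarter of parcels each) so that
    class membership is spatially structured, as on a real cortex.

    Per-vertex inner/outer areas follow a default thickness model in which the
    outer (pial) surface is strictly larger than the inner surface, mimicking
    predominantly gyral sampling.
    """
    if n_parcels < 8:
        raise ValueError("n_parcels must be at least 8")
    if n_parcels % 4 != 0:
        raise ValueError("n_parcels must be divisible by 4 (one quarter per class)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA71A5]))
    half = n_parcels // 2
    pts_left = fibonacci_sphere(half)
    pts_right = pts_left * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([pts_left, pts_right])
    hemispheres = np.array(["L"] * half + ["R"] * (n_parcels - half))
    # contiguous z-bands -> spatially coherent classes, equal sizes
    order = np.argsort(centroids[:, 2])[::-1]
    class_labels = np.empty(n_parcels, dtype=object)
    per_class = n_parcels // 4
    for k, label in enumerate(CLASSES):
        class_labels[order[k * per_class:(k + 1) * per_class]] = label
    parcel_ids = np.array([f"parcel_{i:04d}" for i in range(n_parcels)])
    atlas = ParcelAtlas(parcel_ids, class_labels.astype(str), centroids, hemispheres)

    n_vertices = n_parcels * vertices_per_parcel
    vertex_parcel = np.repeat(np.arange(n_parcels), vertices_per_parcel)
    area_inner = rng.lognormal(mean=np.log(0.5), sigma=0.2, size=n_vertices)
    expansion = rng.uniform(0.2, 0.8, size=n_vertices)  # pial > white everywhere
    area_outer = area_inner * (1.0 + expansion)
    return ToyCortex(atlas, vertex_parcel, area_inner, area_outer)
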