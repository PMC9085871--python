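"""Synthetic cortices, depth profiles, BOLD-like timeseries, and twin cohorts.

The generator encodes the ground truth the pipeline is meant to recover:

* depth profiles follow class-specific quadratic laminar curves plus a fixed
  per-parcel perturbation, subject offsets, and vertex noise — so microstructural
  similarity is class-structured;
* parcel timeseries are drawn from a Gaussian whose correlation blends the
  microstructure-derived similarity S with an independent community structure C,
  with a per-class coupling weight kappa_c in [0, 1] controlling how strongly
  functional connectivity mirrors microstructure in that class;
* twin cohorts follow the additive-genetic/unique-environment (AE) model:
  phenotype = X beta + g + e with corr(g) = 1 in MZ pairs, 0.5 in DZ pairs.

All randomness flows from ``spec.seed`` (or an explicit ``seed``) through named
substreams, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import CLASSES, ParcelAtlas, ToyCortex, make_toy_cortex
from .equivolume import equivolumetric_fraction, make_fraction_grid

logger = logging.getLogger(__name__)

__all__ = [
    "GenerativeSpec",
    "TwinCohort",
    "simulate_depth_profiles",
    "simulate_timeseries",
    "simulate_twin_cohort",
    "microstructure_similarity",
    "hierarchy_position",
    "blend_covariance",
    "random_smooth_map",
]

# substream tags (arbitrary distinct constants)
_STREAMS = {
    "parcel_effects": 1,
    "profiles": 2,
    "community": 3,
    "timeseries": 4,
    "cohort": 5,
    "smooth_map": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


#: class-specific quadratic laminar curves (intercept, slope, curvature) in depth
#: fraction d (0 = pial, 1 = white). Intensity rises towards the white surface,
#: more steeply in heavily myelinated idiotypic cortex, with curvature varying
#: along the sensory-fugal axis so the four classes have distinct profile shapes.
DEFAULT_CLASS_CURVES = {
    "idiotypic": (1.40, 0.90, -0.30),
    "unimodal": (1.30, 0.60, -0.10),
    "heteromodal": (1.20, 0.40, 0.10),
    "paralimbic": (1.10, 0.25, 0.20),
}

#: per-class coupling between functional covariance and microstructural
#: similarity: strong in primary cortex, intermediate in unimodal association
#: cortex, weak in transmodal (heteromodal and paralimbic) cortex.
DEFAULT_KAPPA = {
    "idiotypic": 0.9,
    "unimodal": 0.5,
    "heteromodal": 0.1,
    "paralimbic": 0.1,
}


@dataclass
class GenerativeSpec:
    """Parameters of the synthetic cortex generator.

    Noise scales are in T1w/T2w-like intensity units (class curves span roughly
    1.1-2.0 over depth); ``kappa`` entries live in [0, 1].

    ``hierarchy`` controls how laminar curves vary over the cortex:
    "continuous" (default) interpolates the class curves smoothly along the
    sensory-fugal axis, so microstructural similarity carries one dominant
    gradient, as in real cortex; "class" gives every parcel of a class exactly
    its class curve (a purely block-structured cortex).
    """

    n_parcels: int = 100
    vertices_per_parcel: int = 10
    n_depths: int = 12
    hierarchy: str = "continuous"
    class_curves: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_CURVES))
    parcel_effect_sd: float = 0.08  # fixed per-parcel laminar idiosyncrasy
    n_profile_basis: int = 4  # cosine harmonics carrying the parcel idiosyncrasy
    subject_noise_sd: float = 0.03  # per subject-parcel intensity offset
    vertex_noise_sd: float = 0.05  # per vertex/depth/subject measurement noise
    kappa: dict = field(default_factory=lambda: dict(DEFAULT_KAPPA))
    community_size: int = 10
    community_rho: float = 0.6
    ts_length: int = 400
    ts_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_depths < 2:
            raise ValueError("n_depths must be at least 2")
        for name in ("parcel_effect_sd", "subject_noise_sd", "vertex_noise_sd", "ts_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for cls in CLASSES:
            if cls not in self.class_curves:
                raise ValueError(f"missing class curve for {cls!r}")
            k = self.kappa.get(cls)
            if k is None or not (0.0 <= k <= 1.0):
                raise ValueError(f"kappa[{cls!r}] must lie in [0, 1]")
        if self.ts_length < 50:
            raise ValueError("ts_length must be at least 50")
        if self.hierarchy not in ("continuous", "class"):
            raise ValueError("hierarchy must be 'continuous' or 'class'")
        if self.n_profile_basis < 1:
            raise ValueError("n_profile_basis must be at least 1")

    def make_cortex(self) -> ToyCortex:
        return make_toy_cortex(self.n_parcels, self.seed,
                               vertices_per_parcel=self.vertices_per_parcel)


def hierarchy_position(atlas: ParcelAtlas) -> np.ndarray:
    """Sensory-fugal position t in (0, 1) per parcel.

    t is the normalized rank of the parcel along the class-band axis
    (descending z), so t increases from the idiotypic to the paralimbic end
    and class membership corresponds to the four quarters of t.
    """
    n = atlas.n_parcels
    order = np.argsort(atlas.centroids[:, 2])[::-1]
    t = np.empty(n)
    t[order] = (np.arange(n) + 0.5) / n
    return t


def _parcel_curve_coefs(atlas: ParcelAtlas, spec: GenerativeSpec) -> np.ndarray:
    """(n_parcels, 3) quadratic laminar coefficients per parcel.

    With ``hierarchy='continuous'`` the class curves act as knots at the band
    centres t = 1/8, 3/8, 5/8, 7/8 of the sensory-fugal axis and coefficients
    are linearly interpolated between them, so laminar structure drifts
    smoothly along the hierarchy. With ``hierarchy='class'`` every parcel gets
    exactly its class curve.
    """
    if spec.hierarchy == "continuous":
        knots = np.array([0.125, 0.375, 0.625, 0.875])
        curves = np.array([spec.class_curves[c] for c in CLASSES], dtype=float)
        t = hierarchy_position(atlas)
        return np.column_stack([np.interp(t, knots, curves[:, j]) for j in range(3)])
    return np.array([spec.class_curves[c] for c in atlas.class_labels], dtype=float)


def _parcel_signature_coefs(atlas: ParcelAtlas, spec: GenerativeSpec) -> np.ndarray:
    """(n_parcels, n_profile_basis) fixed laminar idiosyncrasy coefficients.

    Each parcel carries a fixed smooth perturbation of its laminar curve,
    expressed on the cosine basis cos(k*pi*d), k = 1..n_profile_basis. Using a
    multi-dimensional basis (rather than perturbing the three quadratic
    coefficients) keeps the residual profile space full-rank, so partial
    correlations between parcel profiles stay away from +-1.
    """
    rng = _rng(spec.seed, "parcel_effects")
    return rng.normal(0.0, spec.parcel_effect_sd,
                      size=(atlas.n_parcels, spec.n_profile_basis))


def _eval_signature(coefs: np.ndarray, d: np.ndarray) -> np.ndarray:
    """coefs (m, K), d (m, k) -> (m, k): sum_k c_k cos(k*pi*d)."""
    out = np.zeros_like(d, dtype=float)
    for k in range(coefs.shape[1]):
        out += coefs[:, k:k + 1] * np.cos((k + 1) * np.pi * d)
    return out


def _vertex_base_profiles(cortex: ToyCortex, spec: GenerativeSpec) -> np.ndarray:
    """(n_vertices, n_depths) noise-free vertex profiles: curve + parcel signature."""
    coefs = _parcel_curve_coefs(cortex.atlas, spec)
    sig = _parcel_signature_coefs(cortex.atlas, spec)
    fr = _vertex_fractions(cortex, spec)
    return (_eval_quadratic(coefs[cortex.vertex_parcel], fr)
            + _eval_signature(sig[cortex.vertex_parcel], fr))


def _vertex_fractions(cortex: ToyCortex, spec: GenerativeSpec) -> np.ndarray:
    """(n_vertices, n_depths) equivolumetric depth fractions per vertex."""
    alphas = make_fraction_grid(spec.n_depths)
    return equivolumetric_fraction(
        cortex.area_inner[:, None], cortex.area_outer[:, None], alphas[None, :]
    )


def _eval_quadratic(coefs: np.ndarray, d: np.ndarray) -> np.ndarray:
    """coefs (m, 3), d (m, k) -> (m, k)."""
    a, b, c = coefs[:, 0:1], coefs[:, 1:2], coefs[:, 2:3]
    return a + b * d + c * d**2


def expected_parcel_profiles(cortex: ToyCortex, spec: GenerativeSpec) -> np.ndarray:
    """Noise-free parcel mean profiles (n_parcels, n_depths)."""
    vp = _vertex_base_profiles(cortex, spec)
    out = np.empty((cortex.atlas.n_parcels, spec.n_depths))
    for p in range(cortex.atlas.n_parcels):
        out[p] = vp[cortex.vertex_parcel == p].mean(axis=0)
    return out


def microstructure_similarity(cortex: ToyCortex, spec: GenerativeSpec) -> np.ndarray:
    """Generative microstructural similarity matrix S (unit diagonal).

    Off-diagonals are the partial correlations of the noise-free parcel depth
    profiles controlling for the cortex-wide mean profile — the population
    quantity the MPC estimator targets. Using the partial form (rather than raw
    profile correlation) keeps the generative functional coupling defined in
    the same similarity space that the microstructural arm of the pipeline
    measures.
    """
    from .connectomes import mpc_subject  # local import avoids a cycle
    from .equivolume import ParcelProfileMatrix

    prof = expected_parcel_profiles(cortex, spec)
    ppm = ParcelProfileMatrix(profiles=prof, parcel_ids=cortex.atlas.parcel_ids)
    S = mpc_subject(ppm).values.copy()
    np.fill_diagonal(S, 1.0)
    return S


def simulate_depth_profiles(
    cortex: ToyCortex, spec: GenerativeSpec, n_subjects: int
) -> list[np.ndarray]:
    """Per-subject vertex-wise depth profiles.

    Each vertex's profile is its parcel's quadratic laminar curve evaluated at
    the vertex's own equivolumetric depth fractions, plus a per-subject/parcel
    intensity offset and i.i.d. vertex noise.

    Returns a list of (n_vertices, n_depths) arrays.
    """
    if cortex.atlas.n_parcels != spec.n_parcels:
        raise ValueError("cortex and spec disagree on parcel count")
    rng = _rng(spec.seed, "profiles")
    base = _vertex_base_profiles(cortex, spec)
    out = []
    for _ in range(n_subjects):
        subj_offset = rng.normal(0.0, spec.subject_noise_sd, size=spec.n_parcels)
        noise = rng.normal(0.0, spec.vertex_noise_sd, size=base.shape)
        out.append(base + subj_offset[cortex.vertex_parcel][:, None] + noise)
    return out


def _community_correlation(n_parcels: int, spec: GenerativeSpec) -> np.ndarray:
    """Independent community-structured correlation matrix C.

    Parcels are partitioned into communities at random, ignoring class
    boundaries, with constant within-community correlation. Block-constant
    compound symmetry keeps C positive semi-definite by construction.
    """
    rng = _rng(spec.seed, "community")
    perm = rng.permutation(n_parcels)
    n_comm = max(1, int(round(n_parcels / spec.community_size)))
    labels = np.empty(n_parcels, dtype=int)
    for k, chunk in enumerate(np.array_split(perm, n_comm)):
        labels[chunk] = k
    C = np.where(labels[:, None] == labels[None, :], spec.community_rho, 0.0)
    np.fill_diagonal(C, 1.0)
    return C


def blend_covariance(S: np.ndarray, C: np.ndarray, kappa_parcel: np.ndarray) -> np.ndarray:
    """Blend microstructural similarity with community structure.

    Within a class c the blend is kappa_c * S + (1 - kappa_c) * C; across
    classes the weight is the geometric mean sqrt(kappa_c * kappa_c'). If the
    blend is not positive definite it is regularized by diagonal loading
    (rescaled back to unit diagonal), and the loading is logged.
    """
    kappa_parcel = np.asarray(kappa_parcel, dtype=float)
    G = np.sqrt(np.outer(kappa_parcel, kappa_parcel))
    sigma = G * S + (1.0 - G) * C
    sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    lam_min = float(np.linalg.eigvalsh(sigma)[0])
    if lam_min < 1e-8:
        load = abs(lam_min) + 1e-6
        logger.info("blend covariance not PD (min eig %.3g); diagonal loading %.3g",
                    lam_min, load)
        sigma = (sigma + load * np.eye(sigma.shape[0])) / (1.0 + load)
    return sigma


def functional_covariance(cortex: ToyCortex, spec: GenerativeSpec) -> np.ndarray:
    """The generative correlation matrix of the parcel timeseries (before noise)."""
    S = microstructure_similarity(cortex, spec)
    C = _community_correlation(spec.n_parcels, spec)
    kappa_parcel = np.array([spec.kappa[c] for c in cortex.atlas.class_labels])
    return blend_covariance(S, C, kappa_parcel)


def simulate_timeseries(
    cortex: ToyCortex, spec: GenerativeSpec, n_subjects: int
) -> list[np.ndarray]:
    """Per-subject (T, n_parcels) Gaussian timeseries with the blended covariance."""
    if cortex.atlas.n_parcels != spec.n_parcels:
        raise ValueError("cortex and spec disagree on parcel count")
    sigma = functional_covariance(cortex, spec)
    L = np.linalg.cholesky(sigma)
    rng = _rng(spec.seed, "timeseries")
    out = []
    for _ in range(n_subjects):
        Z = rng.standard_normal((spec.ts_length, spec.n_parcels))
        X = Z @ L.T
        if spec.ts_noise_sd > 0:
            X = X + rng.normal(0.0, spec.ts_noise_sd, size=X.shape)
        out.append(X)
    return out


# ---------------------------------------------------------------------------
# twin cohorts


@dataclass
class TwinCohort:
    """A pedigree of MZ/DZ twin pairs and singletons with phenotypes.

    ``pedigree`` has columns subject_id, family_id, zygosity, age, sex;
    ``phenotypes`` is a (n_subjects, n_phenotypes) DataFrame aligned to it.
    """

    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"subject_id", "family_id", "zygosity", "age", "sex"}
        if not req <= set(self.pedigree.columns):
            raise ValueError(f"pedigree missing columns {sorted(req - set(self.pedigree.columns))}")
        if np.any(self.pedigree["age"].to_numpy() <= 0):
            raise ValueError("ages must be positive")
        sizes = self.pedigree.groupby("family_id").size()
        zyg = self.pedigree.groupby("family_id")["zygosity"].first()
        if np.any(sizes[zyg.isin(["MZ", "DZ"])] != 2):
            raise ValueError("MZ/DZ families must contain exactly 2 members")
        if np.any(sizes[zyg == "singleton"] != 1):
            raise ValueError("singletons must be sole members of their family")
        if len(self.phenotypes) != len(self.pedigree):
            raise ValueError("phenotype rows must match pedigree rows")

    @property
    def n_subjects(self) -> int:
        return len(self.pedigree)

    def pairs(self, zygosity: str) -> list[tuple[int, int]]:
        """Row-index pairs of twins of the given zygosity."""
        out = []
        sub = self.pedigree.reset_index(drop=True)
        for _, grp in sub[sub["zygosity"] == zygosity].groupby("family_id"):
            idx = grp.index.to_numpy()
            if idx.size == 2:
                out.append((int(idx[0]), int(idx[1])))
        return out

    def to_csv(self, pedigree_path, phenotype_path=None) -> None:
        self.pedigree.to_csv(pedigree_path, index=False)
        if phenotype_path is not None:
            self.phenotypes.to_csv(phenotype_path, index=False)

    @classmethod
    def from_csv(cls, pedigree_path, phenotype_path=None) -> "TwinCohort":
        ped = pd.read_csv(pedigree_path)
        if phenotype_path is not None:
            phen = pd.read_csv(phenotype_path)
        else:
            phen = pd.DataFrame(index=range(len(ped)))
        return cls(ped, phen)


#: modest covariate effects on the phenotype scale (intercept, centered age,
#: sex, centered age squared, centered age x sex)
DEFAULT_COVARIATE_BETAS = (0.0, 0.05, 0.2, 0.01, 0.02)


def simulate_twin_cohort(
    n_mz_pairs: int = 149,
    n_dz_pairs: int = 94,
    n_singletons: int = 720,
    h2_true=0.5,
    covariate_betas=DEFAULT_COVARIATE_BETAS,
    seed: int = 0,
    sigma2_p: float = 1.0,
    n_phenotypes: int = 1,
    phenotype_names=None,
    age_range: tuple[float, float] = (22.0, 37.0),
) -> TwinCohort:
    """Simulate an AE twin cohort with known heritability.

    Each phenotype is X beta + g + e with Var(g) = h2 * sigma2_p,
    Var(e) = (1 - h2) * sigma2_p; the additive-genetic value g is shared within
    MZ pairs and correlated 0.5 within DZ pairs. ``h2_true`` may be a scalar or
    one value per phenotype. Default family counts mirror a large young-adult
    twin sample (149 MZ pairs, 94 DZ pairs, 720 singletons).
    """
    h2 = np.atleast_1d(np.asarray(h2_true, dtype=float))
    if h2.size == 1:
        h2 = np.full(n_phenotypes, h2[0])
    if h2.size != n_phenotypes:
        raise ValueError("h2_true must be scalar or one value per phenotype")
    if np.any(h2 < 0) or np.any(h2 > 1):
        raise ValueError("h2_true must lie in [0, 1]")
    beta = np.asarray(covariate_betas, dtype=float)
    if beta.size != 5:
        raise ValueError("covariate_betas must have 5 entries")

    rng = _rng(seed, "cohort")
    rows = []
    fam = 0
    for _ in range(n_mz_pairs):
        age = rng.uniform(*age_range)
        sex = int(rng.integers(2))  # MZ co-twins share sex
        for k in range(2):
            rows.append((f"sub_{fam:05d}_{k}", f"fam_{fam:05d}", "MZ", age, sex))
        fam += 1
    for _ in range(n_dz_pairs):
        age = rng.uniform(*age_range)
        for k in range(2):
            rows.append((f"sub_{fam:05d}_{k}", f"fam_{fam:05d}", "DZ", age,
                         int(rng.integers(2))))
        fam += 1
    for _ in range(n_singletons):
        rows.append((f"sub_{fam:05d}_0", f"fam_{fam:05d}", "singleton",
                     rng.uniform(*age_range), int(rng.integers(2))))
        fam += 1
    ped = pd.DataFrame(rows, columns=["subject_id", "family_id", "zygosity", "age", "sex"])

    from .heritability import build_design  # local import to avoid cycle at import time

    X = build_design(ped)
    n = len(ped)
    zyg = ped["zygosity"].to_numpy()
    fam_ids = ped["family_id"].to_numpy()

    phen = {}
    names = phenotype_names or [f"phenotype_{j}" for j in range(n_phenotypes)]
    for j, name in enumerate(names):
        sg = np.sqrt(h2[j] * sigma2_p)
        se = np.sqrt((1.0 - h2[j]) * sigma2_p)
        g = np.empty(n)
        i = 0
        while i < n:
            if zyg[i] == "MZ":
                val = rng.normal(0.0, 1.0)
                g[i] = g[i + 1] = val
                i += 2
            elif zyg[i] == "DZ":
                shared = rng.normal(0.0, 1.0)
                g[i] = np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.normal(0.0, 1.0)
                g[i + 1] = np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.normal(0.0, 1.0)
                i += 2
            else:
                g[i] = rng.normal(0.0, 1.0)
                i += 1
        e = rng.normal(0.0, 1.0, size=n)
        phen[name] = X @ beta + sg * g + se * e
    # fam_ids kept for clarity of the generative loop above
    del fam_ids
    return TwinCohort(ped, pd.DataFrame(phen))


# ---------------------------------------------------------------------------
# smooth maps on the sphere (for spin-test calibration and demos)


def random_smooth_map(
    atlas: ParcelAtlas,
    length_scale: float = 0.5,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """A spatially autocorrelated Gaussian map over parcel centroids.

    White noise is smoothed with a geodesic squared-exponential kernel of the
    given length scale (radians) and z-standardized. Right-hemisphere centroids
    are mapped into the left-hemisphere frame (x-flip) before computing
    geodesics, so cross-hemisphere correlation is mirror-homotopic — the same
    symmetry the mirrored spin rotations preserve.
    """
    if rng is None:
        rng = _rng(seed, "smooth_map")
    cent = atlas.centroids.copy()
    cent[atlas.hemispheres == "R"] *= np.array([-1.0, 1.0, 1.0])
    dots = np.clip(cent @ cent.T, -1.0, 1.0)
    theta = np.arccos(dots)
    K = np.exp(-(theta**2) / (2.0 * length_scale**2))
    m = K @ rng.standard_normal(atlas.n_parcels)
    return (m - m.mean()) / m.std()
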