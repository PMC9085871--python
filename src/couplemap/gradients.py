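"""Diffusion-map embedding of connectivity matrices ("gradients").

The pipeline is: row-threshold the connectivity matrix (keep each row's top
decile by default), build a normalized-angle affinity between rows, then embed
with a diffusion map: density-normalize W' = D^-alpha W D^-alpha, form the
Markov operator P = D'^-1 W', and take its leading non-trivial eigenvectors.
``alpha`` controls the influence of sampling density (0 = maximal, 1 = none);
``t`` is diffusion time, with t = 0 interpreted as the multiscale scaling
lambda / (1 - lambda) by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .connectomes import ConnectivityMatrix

__all__ = [
    "threshold_rows",
    "normalized_angle_affinity",
    "diffusion_map",
    "DiffusionGradients",
    "GradientSet",
    "procrustes_align",
    "gradient_difference",
    "select_homolog_gradient",
]


def threshold_rows(matrix, pct: float = 90.0) -> np.ndarray:
    """Keep, per row, the entries at or above that row's ``pct`` percentile.

    Surviving entries retain their values; the rest are zeroed. The result need
    not be symmetric. An all-equal row survives entirely (every entry ties at
    the percentile).
    """
    M = _as_values(matrix)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not (0.0 < pct < 100.0):
        raise ValueError("pct must lie strictly between 0 and 100")
    cut = np.percentile(M, pct, axis=1, keepdims=True)
    return np.where(M >= cut, M, 0.0)


def _as_values(m) -> np.ndarray:
    if isinstance(m, ConnectivityMatrix):
        return np.asarray(m.values, dtype=float)
    return np.asarray(m, dtype=float)


def normalized_angle_affinity(matrix) -> np.ndarray:
    """Normalized-angle similarity between rows: 1 - arccos(cosine) / pi.

    Identical rows map to 1, orthogonal rows to 0.5, anti-parallel rows to 0.
    """
    M = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"row {bad} is all zero; cannot form an angle")
    cos = (M @ M.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    return (aff + aff.T) / 2.0


@dataclass
class GradientSet:
    """Eigenvectors/eigenvalues of a diffusion embedding plus alignment state."""

    components: np.ndarray  # (n_parcels, n_components)
    eigenvalues: np.ndarray  # (n_components,), non-increasing
    kind: str = "generic"  # e.g. "MPC" or "FC"
    alignment: str = "raw"
    standardized: bool = False
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.components.shape[1] != self.eigenvalues.size:
            raise ValueError("components / eigenvalues size mismatch")

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def component(self, k: int) -> np.ndarray:
        """The k-th gradient, 1-based (G1 is the principal gradient)."""
        return self.components[:, k - 1]

    def standardize(self) -> "GradientSet":
        """Z-score each component across parcels (columns with zero variance fail).

        Standardizing before Procrustes alignment puts components on a common
        scale, so the rotation is driven by spatial pattern rather than by the
        eigenvalue-dependent scaling of each component.
        """
        sd = self.components.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("cannot standardize a zero-variance component")
        comps = (self.components - self.components.mean(axis=0)) / sd
        return GradientSet(comps, self.eigenvalues, kind=self.kind,
                           alignment=self.alignment, standardized=True,
                           config=dict(self.config))

    def to_csv(self, path, parcel_ids=None) -> None:
        import pandas as pd

        n = self.components.shape[0]
        if parcel_ids is None:
            parcel_ids = [f"parcel_{i:04d}" for i in range(n)]
        cols = [f"G{k+1}" for k in range(self.n_components)]
        pd.DataFrame(self.components, index=parcel_ids, columns=cols).to_csv(path)
        sidecar = {
            "eigenvalues": self.eigenvalues.tolist(),
            "kind": self.kind,
            "alignment": self.alignment,
            "standardized": self.standardized,
            "config": self.config,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign: each component's largest-|value| entry is positive."""
    out = components.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        if col.size and col[int(np.argmax(np.abs(col)))] < 0:
            out[:, k] = -col
    return out


def _embed_connected(W: np.ndarray, n_components: int, alpha: float,
                     diffusion_time: float, multiscale_at_t0: bool):
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("affinity has a zero-degree node")
    Wa = W / np.outer(d**alpha, d**alpha)
    da = Wa.sum(axis=1)
    # symmetric conjugate of the Markov operator P = Da^-1 Wa
    M = Wa / np.sqrt(np.outer(da, da))
    M = (M + M.T) / 2.0
    n = W.shape[0]
    k = min(n_components, n - 1)
    evals, evecs = linalg.eigh(M)
    order = np.argsort(evals)[::-1][: k + 1]
    lam = evals[order]
    phi = evecs[:, order]
    # The trivial eigenvector of M is exactly u = sqrt(da) (eigenvalue 1). When
    # the top eigenvalue is degenerate (disconnected graph), eigh returns an
    # arbitrary basis of the eigenspace, so pin u explicitly and rotate the
    # rest of that eigenspace into its orthogonal complement.
    u = np.sqrt(da)
    u = u / np.linalg.norm(u)
    deg = np.flatnonzero(np.abs(lam - lam[0]) < 1e-10)
    if deg.size > 1:
        B = phi[:, deg]
        resid = B - np.outer(u, u @ B)
        basis = np.linalg.svd(resid, full_matrices=False)[0][:, : deg.size - 1]
        phi[:, deg[1:]] = basis
    phi[:, 0] = u
    psi = phi / np.sqrt(da)[:, None]
    psi = psi / psi[0, 0]  # normalize against the trivial constant eigenvector
    lam_rest = lam[1:]
    lam_rest = np.where(np.abs(lam_rest) < 1e-12, 0.0, lam_rest)
    if diffusion_time == 0 and multiscale_at_t0:
        lam_c = np.clip(lam_rest, None, 1.0 - 1e-12)
        scale = lam_c / (1.0 - lam_c)
    else:
        scale = lam_rest**diffusion_time
    comps = psi[:, 1:] * scale[None, :]
    return _fix_signs(comps), lam_rest


def diffusion_map(
    affinity,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    multiscale_at_t0: bool = True,
    on_disconnected: str = "global",
    kind: str = "generic",
) -> GradientSet:
    """Diffusion-map embedding of a symmetric non-negative affinity matrix.

    ``diffusion_time = 0`` uses the multiscale eigenvalue scaling
    lambda / (1 - lambda) unless ``multiscale_at_t0`` is False (literal
    lambda**0). Disconnected affinities are embedded globally with a warning by
    default; ``on_disconnected="largest"`` embeds the largest component and
    flags the rest as NaN.
    """
    W = np.asarray(affinity, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if diffusion_time < 0:
        raise ValueError("diffusion time must be non-negative")
    config = {
        "alpha": alpha,
        "t": diffusion_time,
        "multiscale_at_t0": multiscale_at_t0,
        "n_components": n_components,
    }
    n_cc, labels = connected_components(W > 0, directed=False)
    if n_cc > 1:
        warnings.warn(f"affinity graph has {n_cc} connected components",
                      RuntimeWarning, stacklevel=2)
        if on_disconnected == "largest":
            sizes = np.bincount(labels)
            keep = np.flatnonzero(labels == np.argmax(sizes))
            comps_sub, lam = _embed_connected(
                W[np.ix_(keep, keep)], n_components, alpha, diffusion_time,
                multiscale_at_t0,
            )
            comps = np.full((W.shape[0], comps_sub.shape[1]), np.nan)
            comps[keep] = comps_sub
            return GradientSet(comps, lam, kind=kind, config=config)
        if on_disconnected != "global":
            raise ValueError("on_disconnected must be 'global' or 'largest'")
    comps, lam = _embed_connected(W, n_components, alpha, diffusion_time,
                                  multiscale_at_t0)
    return GradientSet(comps, lam, kind=kind, config=config)


class DiffusionGradients(BaseEstimator):
    """Connectome gradients as a scikit-learn style estimator.

    ``fit(X)`` takes a square connectivity matrix (or ConnectivityMatrix),
    row-thresholds it, builds the normalized-angle affinity, and stores the
    diffusion embedding in ``components_`` / ``eigenvalues_``.
    """

    def __init__(self, n_components=10, alpha=0.5, diffusion_time=0.0,
                 row_threshold_pct=90.0, multiscale_at_t0=True,
                 on_disconnected="global"):
        self.n_components = n_components
        self.alpha = alpha
        self.diffusion_time = diffusion_time
        self.row_threshold_pct = row_threshold_pct
        self.multiscale_at_t0 = multiscale_at_t0
        self.on_disconnected = on_disconnected

    def fit(self, X, y=None):
        kind = X.kind if isinstance(X, ConnectivityMatrix) else "generic"
        thr = threshold_rows(X, self.row_threshold_pct)
        aff = normalized_angle_affinity(thr)
        gs = diffusion_map(
            aff, n_components=self.n_components, alpha=self.alpha,
            diffusion_time=self.diffusion_time,
            multiscale_at_t0=self.multiscale_at_t0,
            on_disconnected=self.on_disconnected, kind=kind,
        )
        gs.config["row_threshold_pct"] = self.row_threshold_pct
        self.components_ = gs.components
        self.eigenvalues_ = gs.eigenvalues
        self.affinity_ = aff
        self.gradient_set_ = gs
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).components_


def compute_gradients(matrix, **kwargs) -> GradientSet:
    """Functional wrapper over :class:`DiffusionGradients`."""
    return DiffusionGradients(**kwargs).fit(matrix).gradient_set_


def procrustes_align(source: GradientSet, reference: GradientSet) -> GradientSet:
    """Rotate (orthogonally, reflections allowed, no scaling) source onto reference."""
    S, R = source.components, reference.components
    if S.shape != R.shape:
        raise ValueError("source and reference must share shape")
    try:
        Q, _ = linalg.orthogonal_procrustes(S, R)
        if not np.all(np.isfinite(Q)):
            raise np.linalg.LinAlgError("non-finite rotation")
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient cross-product; falling back to identity",
                      RuntimeWarning, stacklevel=2)
        Q = np.eye(S.shape[1])
    aligned = S @ Q
    return GradientSet(aligned, source.eigenvalues, kind=source.kind,
                       alignment=f"procrustes-to-{reference.kind}",
                       standardized=source.standardized, config=dict(source.config))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("component has zero variance")
    return (v - v.mean()) / sd


def gradient_difference(
    g_mpc: GradientSet, g_fc: GradientSet, component: int = 1,
    atlas=None,
) -> np.ndarray:
    """Nodal difference Delta = z(FC G_k) - z(MPC G_k) of aligned gradients.

    Both components are z-standardized across parcels first. When an atlas is
    given, a single joint sign flip is applied to both maps so that the FC
    (reference) component has a negative idiotypic-class mean — a fixed
    orientation convention for display. The flip is applied jointly because
    Procrustes alignment already placed the two maps in a common frame;
    orienting each map independently would re-introduce an arbitrary relative
    sign whenever the orientation statistic is near zero.
    """
    z_mpc = _zscore(g_mpc.component(component))
    z_fc = _zscore(g_fc.component(component))
    if atlas is not None:
        idx = atlas.class_indices("idiotypic")
        if z_fc[idx].mean() > 0:
            z_fc = -z_fc
            z_mpc = -z_mpc
    return z_fc - z_mpc


def select_homolog_gradient(candidate: GradientSet, reference_map) -> tuple[int, int]:
    """Pick the candidate component best matching a reference map.

    Returns (1-based component index, sign) maximizing the absolute Spearman
    correlation with the reference; ``sign`` is +1/-1 so that
    ``sign * component`` correlates positively with the reference.
    """
    ref = np.asarray(reference_map, dtype=float)
    best_k, best_r = 1, 0.0
    for k in range(1, candidate.n_components + 1):
        r = stats.spearmanr(candidate.component(k), ref).statistic
        if np.isnan(r):
            continue
        if abs(r) > abs(best_r):
            best_k, best_r = k, r
    return best_k, (1 if best_r >= 0 else -1)
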