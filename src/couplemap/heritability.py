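"""Twin-based AE variance decomposition by maximum likelihood.

The model is y ~ N(X beta, sigma2_g * K + sigma2_e * I), where K is the
block-diagonal genetic-correlation (kinship) matrix: off-diagonal 1 within MZ
pairs, 0.5 within DZ pairs, and 1x1 blocks for singletons. Narrow-sense
heritability is h2 = sigma2_g / (sigma2_g + sigma2_e).

Because families are pairs or singletons, each 2x2 block diagonalizes under the
sum/difference rotation of the twins' observations: the transformed variances
are sigma2_p * (1 +/- c * h2) with c the pair's genetic correlation. The whole
likelihood therefore reduces to a weighted least-squares problem per h2, which
is profiled over beta and sigma2_p and maximized over h2 alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "inverse_normal_transform",
    "build_design",
    "KinshipStructure",
    "TwinAE",
    "HeritabilityEstimate",
    "fit_ae",
    "map_heritability",
]


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1(rank / (n + 1)).

    Ties receive average ranks, so the transform preserves ordering and is
    invariant to any strictly monotone re-scaling of the input.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need at least 3 values")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    if np.all(y == y[0]):
        warnings.warn("all values identical; inverse normal transform is degenerate",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(y)
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf(ranks / (y.size + 1))


def build_design(cohort_or_pedigree) -> np.ndarray:
    """Covariate design matrix: intercept, centered age, sex, age^2, age x sex.

    Age is mean-centered before forming the quadratic and interaction terms so
    the columns stay well-conditioned.
    """
    ped = getattr(cohort_or_pedigree, "pedigree", cohort_or_pedigree)
    for col in ("age", "sex"):
        if col not in ped.columns:
            raise ValueError(f"pedigree is missing the {col!r} covariate")
    age = ped["age"].to_numpy(dtype=float)
    sex = ped["sex"].to_numpy(dtype=float)
    age_c = age - age.mean()
    return np.column_stack([np.ones_like(age), age_c, sex, age_c**2, age_c * sex])


@dataclass
class KinshipStructure:
    """Pair/singleton representation of the genetic-correlation matrix.

    ``pair_index`` holds (i, j) row indices of each twin pair, ``pair_coef``
    the corresponding genetic correlation (1 for MZ, 0.5 for DZ), and
    ``singletons`` the remaining row indices.
    """

    pair_index: np.ndarray  # (n_pairs, 2) int
    pair_coef: np.ndarray  # (n_pairs,) float
    singletons: np.ndarray  # (n_single,) int
    n_subjects: int

    @classmethod
    def from_cohort(cls, cohort) -> "KinshipStructure":
        ped = getattr(cohort, "pedigree", cohort).reset_index(drop=True)
        pairs, coefs, seen = [], [], np.zeros(len(ped), dtype=bool)
        for zyg, c in (("MZ", 1.0), ("DZ", 0.5)):
            for _, grp in ped[ped["zygosity"] == zyg].groupby("family_id"):
                idx = grp.index.to_numpy()
                if idx.size != 2:
                    raise ValueError("MZ/DZ family without exactly 2 members")
                pairs.append(idx)
                coefs.append(c)
                seen[idx] = True
        singles = np.flatnonzero(~seen)
        pair_index = np.asarray(pairs, dtype=int).reshape(-1, 2)
        return cls(pair_index, np.asarray(coefs, dtype=float), singles, len(ped))

    def dense(self) -> np.ndarray:
        """The full n x n genetic correlation matrix (for small-cohort oracles)."""
        K = np.eye(self.n_subjects)
        for (i, j), c in zip(self.pair_index, self.pair_coef):
            K[i, j] = K[j, i] = c
        return K


def _transform(kinship: KinshipStructure, X: np.ndarray, y: np.ndarray):
    """Rotate twin pairs to sum/difference coordinates.

    Returns (X_t, y_t, coef_t) where the model covariance is diagonal with
    entries sigma2_p * (1 + coef_t * h2).
    """
    i, j = kinship.pair_index[:, 0], kinship.pair_index[:, 1]
    s2 = 1.0 / np.sqrt(2.0)
    Xs, Xd = s2 * (X[i] + X[j]), s2 * (X[i] - X[j])
    ys, yd = s2 * (y[i] + y[j]), s2 * (y[i] - y[j])
    Xt = np.vstack([Xs, Xd, X[kinship.singletons]])
    yt = np.concatenate([ys, yd, y[kinship.singletons]])
    coef = np.concatenate([
        kinship.pair_coef, -kinship.pair_coef,
        np.zeros(kinship.singletons.size),
    ])
    return Xt, yt, coef


def _profile_loglik(h2: float, Xt, yt, coef):
    """Log-likelihood profiled over beta (GLS) and sigma2_p (ML), plus both."""
    n = yt.size
    w = 1.0 + coef * h2  # relative variances; positive for h2 < 1
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.lstsq(XtWX, Xw.T @ yt, rcond=None)[0]
    resid = yt - Xt @ beta
    sigma2_p = float(resid @ (resid / w)) / n
    if sigma2_p <= 0:
        sigma2_p = np.finfo(float).tiny
    ll = -0.5 * (n * (np.log(2.0 * np.pi * sigma2_p) + 1.0) + np.sum(np.log(w)))
    return ll, beta, sigma2_p


#: h2 is optimized strictly inside [0, 1]; MZ difference components have
#: variance (1 - h2) which must stay positive
_H2_MAX = 1.0 - 1e-9


@dataclass
class HeritabilityEstimate:
    """Result of one AE fit."""

    h2: float
    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    beta: np.ndarray
    loglik: float
    p_value: float
    se_h2: float
    converged: bool = True

    def __post_init__(self) -> None:
        assert abs(self.h2 - self.sigma2_g / self.sigma2_p) < 1e-9


class TwinAE(BaseEstimator):
    """Maximum-likelihood AE (additive genetic + unique environment) model.

    Scikit-learn style estimator: ``fit(X, y, kinship=...)`` with X the
    covariate design matrix. Fitted attributes carry a trailing underscore.

    Parameters
    ----------
    multi_start : tuple of float
        Interior starting values for h2; the likelihood is maximized over the
        logit of h2 from each start, and the h2 = 0 boundary is checked
        explicitly. Ties go to the highest log-likelihood, then the smallest h2.
    """

    def __init__(self, multi_start=(0.1, 0.5, 0.9)):
        self.multi_start = multi_start

    def fit(self, X, y, *, kinship: KinshipStructure):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_subjects, n_covariates) matching y")
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype must be finite")
        if kinship.pair_index.shape[0] < 2:
            raise ValueError("heritability is unidentifiable without at least 2 twin pairs")

        Xt, yt, coef = _transform(kinship, X, y)

        def nll_logit(z) -> float:
            h2 = float(stats.logistic.cdf(np.asarray(z).ravel()[0]))
            h2 = min(h2, _H2_MAX)
            return -_profile_loglik(h2, Xt, yt, coef)[0]

        candidates = []
        for h0 in self.multi_start:
            z0 = float(stats.logistic.ppf(h0))
            res = optimize.minimize(nll_logit, x0=[z0], method="BFGS",
                                    options={"gtol": 1e-8})
            h2_hat = min(float(stats.logistic.cdf(res.x[0])), _H2_MAX)
            candidates.append((-res.fun, h2_hat, bool(res.success)))
        # explicit boundary candidates
        for h2_b in (0.0, _H2_MAX):
            ll, _, _ = _profile_loglik(h2_b, Xt, yt, coef)
            candidates.append((ll, h2_b, True))
        # highest log-likelihood, ties to smallest h2
        candidates.sort(key=lambda t: (-t[0], t[1]))
        ll_hat, h2_hat, converged = candidates[0]
        # collapse numerically-tied optima onto the smallest h2
        tied = [c for c in candidates if c[0] >= ll_hat - 1e-9]
        h2_hat = min(c[1] for c in tied)
        ll_hat, beta, sigma2_p = _profile_loglik(h2_hat, Xt, yt, coef)

        ll0 = _profile_loglik(0.0, Xt, yt, coef)[0]
        lrt = 2.0 * (ll_hat - ll0)
        # boundary null: 0.5 * chi2_0 + 0.5 * chi2_1 mixture
        p = 1.0 if lrt <= 0 else 0.5 * float(stats.chi2.sf(lrt, df=1))

        se = self._se_h2(h2_hat, Xt, yt, coef)
        h2_report = 1.0 if h2_hat >= _H2_MAX else h2_hat
        self.h2_ = h2_report
        self.sigma2_p_ = sigma2_p
        self.sigma2_g_ = h2_report * sigma2_p
        self.sigma2_e_ = (1.0 - h2_report) * sigma2_p
        self.beta_ = beta
        self.loglik_ = ll_hat
        self.p_value_ = p
        self.se_h2_ = se
        self.converged_ = converged
        self.n_subjects_ = y.size
        return self

    @staticmethod
    def _se_h2(h2: float, Xt, yt, coef, step: float = 1e-4) -> float:
        """Standard error from the numerical observed (profile) information."""
        if h2 <= 0.0 or h2 >= _H2_MAX:  # boundary estimate: curvature unreliable
            return float("nan")
        lo, hi = max(h2 - step, 0.0), min(h2 + step, _H2_MAX)
        f = lambda h: _profile_loglik(h, Xt, yt, coef)[0]
        d2 = (f(hi) - 2.0 * f(h2) + f(lo)) / ((0.5 * (hi - lo)) ** 2)
        if d2 >= 0:
            return float("nan")
        return float(1.0 / np.sqrt(-d2))

    def estimate_(self) -> HeritabilityEstimate:
        return HeritabilityEstimate(
            h2=self.h2_, sigma2_g=self.sigma2_g_, sigma2_e=self.sigma2_e_,
            sigma2_p=self.sigma2_p_, beta=self.beta_, loglik=self.loglik_,
            p_value=self.p_value_, se_h2=self.se_h2_, converged=self.converged_,
        )


def fit_ae(phenotype, cohort, kinship: KinshipStructure | None = None,
           design: np.ndarray | None = None) -> HeritabilityEstimate:
    """Fit the AE model to one phenotype of a twin cohort."""
    if kinship is None:
        kinship = KinshipStructure.from_cohort(cohort)
    if design is None:
        design = build_design(cohort)
    model = TwinAE().fit(design, np.asarray(phenotype, dtype=float), kinship=kinship)
    return model.estimate_()


def map_heritability(
    phenotypes, cohort, kinship: KinshipStructure | None = None,
    transform: bool = True,
) -> pd.DataFrame:
    """Per-phenotype heritability over a collection (nodes or edges).

    Applies the inverse normal transform to each phenotype before fitting.
    Failures are recorded as NaN rows (flagged in ``ok``) rather than aborting
    the whole map.

    Parameters
    ----------
    phenotypes : DataFrame or (n_subjects, n_phenotypes) array
    """
    if kinship is None:
        kinship = KinshipStructure.from_cohort(cohort)
    design = build_design(cohort)
    if isinstance(phenotypes, pd.DataFrame):
        names = list(phenotypes.columns)
        values = phenotypes.to_numpy(dtype=float)
    else:
        values = np.asarray(phenotypes, dtype=float)
        names = [f"phenotype_{j}" for j in range(values.shape[1])]
    rows = []
    for j, name in enumerate(names):
        try:
            y = values[:, j]
            if transform:
                y = inverse_normal_transform(y)
            est = TwinAE().fit(design, y, kinship=kinship).estimate_()
            rows.append((name, est.h2, est.p_value, est.se_h2, True))
        except Exception as exc:  # noqa: BLE001 - per-phenotype failures are flagged
            warnings.warn(f"heritability fit failed for {name}: {exc}",
                          RuntimeWarning, stacklevel=2)
            rows.append((name, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["phenotype", "h2", "p", "se_h2", "ok"]).set_index(
        "phenotype"
    )


def edge_h2_matrix(h2_values, n_parcels: int, edge_index) -> np.ndarray:
    """Fold per-edge h2 values into a symmetric parcel matrix (diagonal 0)."""
    M = np.zeros((n_parcels, n_parcels))
    for (i, j), v in zip(edge_index, np.asarray(h2_values, dtype=float)):
        M[i, j] = M[j, i] = v
    return M
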