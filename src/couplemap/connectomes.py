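"""Microstructure profile covariance (MPC) and resting-state FC matrices.

MPC(i, j) is the partial correlation of the depth profiles of parcels i and j,
controlling for the cortex-wide mean profile c:

    MPC(i, j) = (r_ij - r_ic * r_jc) / sqrt((1 - r_ic**2) * (1 - r_jc**2))

averaged over subjects. rsFC is the Fisher-z-transformed Pearson correlation of
parcel timeseries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equivolume import ParcelProfileMatrix

__all__ = ["ConnectivityMatrix", "mpc_subject", "mpc_group", "fc_subject", "fc_group"]

#: correlations are clipped to +/-(1 - CLIP) before atanh to keep FC finite
_R_CLIP = 1e-7


@dataclass
class ConnectivityMatrix:
    """A symmetric parcel-by-parcel connectivity matrix.

    ``kind`` is "MPC" or "FC_z"; the diagonal is set to 0 by convention and
    excluded from all row-wise statistics downstream.
    """

    values: np.ndarray
    kind: str
    subject: str = "group-mean"
    parcel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        off = self.values[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal values must be finite")
        if self.kind not in ("MPC", "FC_z"):
            raise ValueError("kind must be 'MPC' or 'FC_z'")
        if self.parcel_ids is None:
            self.parcel_ids = np.array([f"parcel_{i:04d}" for i in range(n)])
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=str)
        if self.parcel_ids.size != n:
            raise ValueError("parcel_ids length mismatch")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def row(self, i: int, exclude_diagonal: bool = True) -> np.ndarray:
        r = self.values[i]
        if exclude_diagonal:
            return np.delete(r, i)
        return r

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.parcel_ids, columns=self.parcel_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, kind: str, subject: str = "group-mean") -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), kind=kind, subject=subject, parcel_ids=df.index.to_numpy())


def mpc_subject(profiles: ParcelProfileMatrix) -> ConnectivityMatrix:
    """Subject-level MPC from a parcel-by-depth profile matrix.

    Partials out the cortex-wide mean profile from every pairwise profile
    correlation. Negative values are retained; the diagonal is set to 0.
    """
    P = profiles.profiles
    n_parcels, n_depths = P.shape
    if n_depths < 3:
        raise ValueError("need at least 3 depths for profile correlations")
    sd = P.std(axis=1)
    if np.any(sd == 0):
        bad = profiles.parcel_ids[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"parcel {bad} has a constant depth profile")
    c = profiles.mean_profile
    # correlations of all parcel profiles with each other and with c
    stack = np.vstack([P, c])
    R = np.corrcoef(stack)
    r_pp = R[:n_parcels, :n_parcels]
    r_pc = R[:n_parcels, n_parcels]
    if np.any(np.abs(r_pc) >= 1.0 - 1e-12):
        bad = profiles.parcel_ids[np.flatnonzero(np.abs(r_pc) >= 1.0 - 1e-12)[0]]
        raise ValueError(
            f"parcel {bad} is perfectly correlated with the cortex-wide mean profile"
        )
    denom = np.sqrt(np.outer(1.0 - r_pc**2, 1.0 - r_pc**2))
    mpc = (r_pp - np.outer(r_pc, r_pc)) / denom
    mpc = (mpc + mpc.T) / 2.0
    np.fill_diagonal(mpc, 0.0)
    return ConnectivityMatrix(mpc, kind="MPC", subject=profiles.subject or "subject",
                              parcel_ids=profiles.parcel_ids)


def _check_same_order(matrices) -> np.ndarray:
    ref = matrices[0].parcel_ids
    for m in matrices[1:]:
        if not np.array_equal(m.parcel_ids, ref):
            raise ValueError("subject matrices have mismatched parcel order")
    return ref


def mpc_group(subject_mpcs) -> ConnectivityMatrix:
    """Element-wise mean of subject MPC matrices (the subject average of Eq. form)."""
    subject_mpcs = list(subject_mpcs)
    if not subject_mpcs:
        raise ValueError("need at least one subject")
    ref = _check_same_order(subject_mpcs)
    mean = np.mean([m.values for m in subject_mpcs], axis=0)
    return ConnectivityMatrix(mean, kind="MPC", subject="group-mean", parcel_ids=ref)


def fc_subject(timeseries, parcel_ids=None, subject: str = "subject") -> ConnectivityMatrix:
    """Fisher-z connectivity from a (timepoints, parcels) timeseries array."""
    X = np.asarray(timeseries, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("timeseries must be (T, parcels) with T >= 3")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = parcel_ids[bad] if parcel_ids is not None else str(bad)
        raise ValueError(f"parcel {name} has a constant timeseries")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0 + _R_CLIP, 1.0 - _R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, kind="FC_z", subject=subject, parcel_ids=parcel_ids)


def fc_group(subject_fcs) -> ConnectivityMatrix:
    """Element-wise mean of subject Fisher-z FC matrices."""
    subject_fcs = list(subject_fcs)
    if not subject_fcs:
        raise ValueError("need at least one subject")
    ref = _check_same_order(subject_fcs)
    mean = np.mean([m.values for m in subject_fcs], axis=0)
    return ConnectivityMatrix(mean, kind="FC_z", subject="group-mean", parcel_ids=ref)
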