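"""End-to-end convenience pipeline over synthetic cohorts.

Chains the stages: simulate depth profiles and timeseries, build group MPC and
rsFC matrices, compute node-wise structure-function coupling, class summaries,
gradients, and the gradient-difference map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ToyCortex
from .connectomes import ConnectivityMatrix, fc_group, fc_subject, mpc_group, mpc_subject
from .coupling import class_contrast, class_summary, rowwise_coupling
from .equivolume import parcel_mean_profiles
from .gradients import DiffusionGradients, GradientSet, gradient_difference, procrustes_align
from .synthetic import GenerativeSpec, simulate_depth_profiles, simulate_timeseries

__all__ = ["CouplingResult", "run_coupling_pipeline", "build_group_matrices",
           "gradient_delta"]


@dataclass
class CouplingResult:
    cortex: ToyCortex
    mpc: ConnectivityMatrix
    fc: ConnectivityMatrix
    coupling: np.ndarray
    summary: pd.DataFrame


def build_group_matrices(
    cortex: ToyCortex, spec: GenerativeSpec, n_subjects: int
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Simulate a cohort and return group-mean MPC and rsFC matrices."""
    vertex_profiles = simulate_depth_profiles(cortex, spec, n_subjects)
    mpcs = []
    for s, vp in enumerate(vertex_profiles):
        ppm = parcel_mean_profiles(vp, cortex.vertex_parcel, atlas=cortex.atlas,
                                   subject=f"sub_{s:03d}")
        mpcs.append(mpc_subject(ppm))
    mpc = mpc_group(mpcs)
    ts = simulate_timeseries(cortex, spec, n_subjects)
    fcs = [fc_subject(x, parcel_ids=cortex.atlas.parcel_ids, subject=f"sub_{s:03d}")
           for s, x in enumerate(ts)]
    fc = fc_group(fcs)
    return mpc, fc


def run_coupling_pipeline(spec: GenerativeSpec, n_subjects: int = 10) -> CouplingResult:
    """Full synthetic run: cohort -> group matrices -> coupling -> class summary."""
    cortex = spec.make_cortex()
    mpc, fc = build_group_matrices(cortex, spec, n_subjects)
    coupling = rowwise_coupling(mpc, fc)
    summary = class_summary(coupling, cortex.atlas)
    return CouplingResult(cortex=cortex, mpc=mpc, fc=fc, coupling=coupling,
                          summary=summary)


def gradient_delta(
    mpc: ConnectivityMatrix, fc: ConnectivityMatrix, atlas=None,
    n_components: int = 10, **gradient_kwargs,
) -> tuple[np.ndarray, GradientSet, GradientSet]:
    """Principal-gradient difference map Delta = z(FC G1) - z(MPC G1).

    Both gradient sets are standardized (each component z-scored) and the MPC
    set is then Procrustes-rotated onto the FC reference before subtraction.
    """
    g_fc = DiffusionGradients(n_components=n_components, **gradient_kwargs).fit(fc).gradient_set_.standardize()
    g_mpc = DiffusionGradients(n_components=n_components, **gradient_kwargs).fit(mpc).gradient_set_.standardize()
    g_mpc_aligned = procrustes_align(g_mpc, g_fc)
    delta = gradient_difference(g_mpc_aligned, g_fc, component=1, atlas=atlas)
    return delta, g_mpc_aligned, g_fc


def coupling_class_ordering_ok(summary: pd.DataFrame, margin: float = 0.0) -> bool:
    """Whether class-mean coupling follows idiotypic > unimodal > transmodal."""
    m = summary["mean"]
    return bool(
        m["idiotypic"] > m["unimodal"] + margin
        and m["unimodal"] > max(m["heteromodal"], m["paralimbic"]) + margin
    )


def idiotypic_vs_heteromodal(coupling, atlas) -> tuple[float, float]:
    """Welch contrast of coupling between idiotypic and heteromodal parcels."""
    return class_contrast(coupling, atlas, "idiotypic", "heteromodal")
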