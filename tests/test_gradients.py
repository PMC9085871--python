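import json

import numpy as np
import pytest
import scipy.linalg as sla
from scipy import stats

from couplemap.gradients import (
    DiffusionGradients,
    GradientSet,
    compute_gradients,
    diffusion_map,
    gradient_difference,
    normalized_angle_affinity,
    procrustes_align,
    select_homolog_gradient,
    threshold_rows,
)


def random_affinity(rng, n=50):
    """Random symmetric positive affinity with unit diagonal."""
    A = rng.uniform(0.1, 1.0, size=(n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


def dense_diffusion_oracle(W, alpha=0.5):
    """Dense eigendecomposition of the literally-constructed Markov operator.

    Returns eigenvalues (descending) and eigenvectors of P = D'^-1 W' with
    W' = D^-alpha W D^-alpha, via scipy.linalg.eig on the non-symmetric P.
    """
    d = W.sum(axis=1)
    Wa = W / np.outer(d**alpha, d**alpha)
    P = Wa / Wa.sum(axis=1, keepdims=True)
    evals, evecs = sla.eig(P)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


class TestThresholdRows:
    def test_against_bruteforce_oracle(self, rng):
        M = rng.normal(size=(13, 13))
        out = threshold_rows(M, 90.0)
        for i in range(13):
            cut = np.percentile(M[i], 90.0)
            for j in range(13):
                if M[i, j] >= cut:
                    assert out[i, j] == M[i, j]
                else:
                    assert out[i, j] == 0.0

    def test_keeps_top_decile_count(self, rng):
        M = rng.normal(size=(100, 100))
        out = threshold_rows(M, 90.0)
        kept = (out != 0).sum(axis=1)
        # with 100 entries per row the 90th percentile keeps 10-11 entries
        assert np.all((kept >= 10) & (kept <= 11))

    def test_all_equal_row_survives(self):
        M = np.full((4, 4), 2.0)
        out = threshold_rows(M, 90.0)
        np.testing.assert_array_equal(out, M)

    def test_invalid_pct(self, rng):
        with pytest.raises(ValueError):
            threshold_rows(rng.normal(size=(4, 4)), 0.0)
        with pytest.raises(ValueError):
            threshold_rows(rng.normal(size=(4, 4)), 100.0)


class TestNormalizedAngleAffinity:
    def test_trivial_angles(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 0.0], [-3.0, 0.0]])
        aff = normalized_angle_affinity(M)
        assert aff[0, 2] == pytest.approx(1.0)  # parallel
        assert aff[0, 1] == pytest.approx(0.5)  # orthogonal
        assert aff[0, 3] == pytest.approx(0.0)  # anti-parallel

    def test_zero_row_errors_with_index(self):
        M = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="row 1"):
            normalized_angle_affinity(M)

    def test_symmetric_unit_diagonal(self, rng):
        aff = normalized_angle_affinity(rng.normal(size=(8, 5)))
        np.testing.assert_allclose(aff, aff.T)
        np.testing.assert_allclose(np.diag(aff), 1.0)


class TestDiffusionMap:
    def test_matches_dense_oracle(self, rng):
        # eigenvalues and principal subspace against scipy.linalg.eig on the
        # literally-constructed Markov operator
        for _ in range(20):
            W = random_affinity(rng)
            gs = diffusion_map(W, n_components=5)
            lam_o, vec_o = dense_diffusion_oracle(W)
            np.testing.assert_allclose(gs.eigenvalues, lam_o[1:6], atol=1e-10)
            angles = sla.subspace_angles(gs.components, vec_o[:, 1:6])
            assert np.max(angles) < 1e-6

    def test_permutation_equivariance_up_to_sign(self, rng):
        W = random_affinity(rng, n=30)
        perm = rng.permutation(30)
        g1 = diffusion_map(W, n_components=4)
        g2 = diffusion_map(W[np.ix_(perm, perm)], n_components=4)
        for k in range(1, 5):
            a, b = g1.component(k)[perm], g2.component(k)
            assert (np.allclose(a, b, atol=1e-8)
                    or np.allclose(a, -b, atol=1e-8))

    def test_sign_convention(self, rng):
        W = random_affinity(rng, n=20)
        gs = diffusion_map(W, n_components=4)
        for k in range(1, 5):
            col = gs.component(k)
            assert col[int(np.argmax(np.abs(col)))] > 0

    def test_multiscale_t0_scaling(self, rng):
        W = random_affinity(rng, n=20)
        ms = diffusion_map(W, n_components=3, diffusion_time=0.0)
        raw = diffusion_map(W, n_components=3, diffusion_time=0.0,
                            multiscale_at_t0=False)
        lam = ms.eigenvalues
        # multiscale components = raw (lambda^0-scaled) components * lam/(1-lam)
        for k in range(3):
            np.testing.assert_allclose(
                ms.components[:, k],
                raw.components[:, k] * lam[k] / (1 - lam[k]),
                atol=1e-10,
            )

    def test_disconnected_blocks_global_default(self):
        # two disconnected equal blocks: component 1 is piecewise-constant with
        # opposite signs per block and eigenvalue 1
        W = np.zeros((8, 8))
        W[:4, :4] = 0.8
        W[4:, 4:] = 0.8
        with pytest.warns(RuntimeWarning, match="connected components"):
            gs = diffusion_map(W, n_components=3)
        g1 = gs.component(1)
        assert gs.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(g1[:4], g1[0]) and np.allclose(g1[4:], g1[4])
        assert np.sign(g1[0]) != np.sign(g1[4])

    def test_disconnected_largest_flags_nan(self):
        W = np.zeros((9, 9))
        W[:6, :6] = 0.5
        W[6:, 6:] = 0.5
        with pytest.warns(RuntimeWarning):
            gs = diffusion_map(W, n_components=2, on_disconnected="largest")
        assert np.all(np.isnan(gs.components[6:]))
        assert np.all(np.isfinite(gs.components[:6]))

    def test_validation(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            diffusion_map(rng.normal(size=(4, 4)))
        W = random_affinity(rng, n=5)
        with pytest.raises(ValueError, match="alpha"):
            diffusion_map(W, alpha=1.5)
        with pytest.raises(ValueError, match="time"):
            diffusion_map(W, diffusion_time=-1.0)


class TestDiffusionGradientsEstimator:
    def test_fit_sets_attributes(self, rng):
        M = random_affinity(rng, n=40)
        est = DiffusionGradients(n_components=4).fit(M)
        assert est.components_.shape == (40, 4)
        assert est.eigenvalues_.size == 4
        assert est.gradient_set_.config["row_threshold_pct"] == 90.0

    def test_functional_wrapper_equivalent(self, rng):
        M = random_affinity(rng, n=30)
        gs = compute_gradients(M, n_components=3)
        est = DiffusionGradients(n_components=3).fit(M)
        np.testing.assert_allclose(gs.components, est.components_)

    def test_get_params_roundtrip(self):
        params = DiffusionGradients(alpha=0.3).get_params()
        assert params["alpha"] == 0.3
        assert params["row_threshold_pct"] == 90.0


class TestGradientSet:
    def test_standardize(self, rng):
        gs = GradientSet(rng.normal(size=(20, 3)) * [1.0, 10.0, 0.1],
                         np.array([0.3, 0.2, 0.1]))
        std = gs.standardize()
        np.testing.assert_allclose(std.components.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.components.std(axis=0), 1.0, atol=1e-12)
        assert std.standardized and not gs.standardized

    def test_csv_with_sidecar(self, tmp_path, rng):
        gs = GradientSet(rng.normal(size=(5, 2)), np.array([0.4, 0.2]), kind="MPC")
        p = tmp_path / "grads.csv"
        gs.to_csv(p)
        sidecar = json.loads((tmp_path / "grads.csv.json").read_text())
        assert sidecar["kind"] == "MPC"
        np.testing.assert_allclose(sidecar["eigenvalues"], [0.4, 0.2])


class TestProcrustes:
    def test_recovers_planted_rotation(self, rng):
        ref = rng.normal(size=(50, 6))
        Q = sla.qr(rng.normal(size=(6, 6)))[0]  # random orthogonal matrix
        src = ref @ Q.T
        a = GradientSet(src, np.ones(6))
        b = GradientSet(ref, np.ones(6))
        aligned = procrustes_align(a, b)
        disparity = np.sum((aligned.components - ref) ** 2)
        assert disparity < 1e-10

    def test_alignment_label(self, rng):
        a = GradientSet(rng.normal(size=(10, 2)), np.ones(2), kind="MPC")
        b = GradientSet(rng.normal(size=(10, 2)), np.ones(2), kind="FC_z")
        assert procrustes_align(a, b).alignment == "procrustes-to-FC_z"

    def test_shape_mismatch(self, rng):
        a = GradientSet(rng.normal(size=(10, 2)), np.ones(2))
        b = GradientSet(rng.normal(size=(10, 3)), np.ones(3))
        with pytest.raises(ValueError):
            procrustes_align(a, b)


class TestGradientDifference:
    def test_zero_for_identical_sets(self, rng):
        comps = rng.normal(size=(30, 3))
        g = GradientSet(comps, np.ones(3))
        np.testing.assert_allclose(gradient_difference(g, g), 0.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        comps = rng.normal(size=(30, 3))
        g1 = GradientSet(comps, np.ones(3))
        g2 = GradientSet(comps * 7.0, np.ones(3))
        np.testing.assert_allclose(gradient_difference(g1, g2), 0.0, atol=1e-12)

    def test_joint_orientation_with_atlas(self, cortex100, rng):
        comps = rng.normal(size=(100, 2))
        g = GradientSet(comps, np.ones(2))
        delta_plain = gradient_difference(g, g)
        delta_oriented = gradient_difference(g, g, atlas=cortex100.atlas)
        # joint flip cannot create a difference for identical inputs
        np.testing.assert_allclose(delta_plain, 0.0, atol=1e-12)
        np.testing.assert_allclose(delta_oriented, 0.0, atol=1e-12)


class TestSelectHomolog:
    def test_finds_component_and_sign(self, rng):
        comps = rng.normal(size=(40, 4))
        gs = GradientSet(comps, np.ones(4))
        ref = -comps[:, 2] + 0.01 * rng.normal(size=40)
        k, sign = select_homolog_gradient(gs, ref)
        assert k == 3 and sign == -1
        r = stats.spearmanr(sign * gs.component(k), ref).statistic
        assert r > 0.9
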