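import numpy as np
import pytest

from couplemap.atlas import CLASSES
from couplemap.connectomes import fc_subject, mpc_subject
from couplemap.coupling import rowwise_coupling
from couplemap.equivolume import parcel_mean_profiles
from couplemap.synthetic import (
    GenerativeSpec,
    TwinCohort,
    expected_parcel_profiles,
    functional_covariance,
    hierarchy_position,
    microstructure_similarity,
    simulate_depth_profiles,
    simulate_timeseries,
    simulate_twin_cohort,
)

UNIFORM_KAPPA = {c: 1.0 for c in CLASSES}


class TestGenerativeSpecValidation:
    def test_defaults_valid(self):
        spec = GenerativeSpec()
        assert spec.n_parcels == 100 and spec.n_depths == 12

    def test_invalid_values(self):
        with pytest.raises(ValueError):
            GenerativeSpec(n_depths=1)
        with pytest.raises(ValueError):
            GenerativeSpec(vertex_noise_sd=-0.1)
        with pytest.raises(ValueError):
            GenerativeSpec(kappa={c: 2.0 for c in CLASSES})
        with pytest.raises(ValueError):
            GenerativeSpec(hierarchy="diagonal")


class TestDeterminism:
    def test_profiles_bit_identical(self, small_spec, small_cortex):
        a = simulate_depth_profiles(small_cortex, small_spec, 2)
        b = simulate_depth_profiles(small_cortex, small_spec, 2)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_timeseries_bit_identical(self, small_spec, small_cortex):
        a = simulate_timeseries(small_cortex, small_spec, 2)
        b = simulate_timeseries(small_cortex, small_spec, 2)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_streams_independent_of_subject_count(self, small_spec, small_cortex):
        # first subject unchanged when more subjects are requested
        one = simulate_depth_profiles(small_cortex, small_spec, 1)[0]
        three = simulate_depth_profiles(small_cortex, small_spec, 3)[0]
        np.testing.assert_array_equal(one, three)


class TestProfiles:
    def test_zero_noise_class_mode_identical_profiles(self):
        # with hierarchy="class", no noise and equal vertex areas, all vertices
        # of a class share one laminar profile
        spec = GenerativeSpec(n_parcels=16, vertices_per_parcel=4, seed=0,
                              hierarchy="class", parcel_effect_sd=0.0,
                              subject_noise_sd=0.0, vertex_noise_sd=0.0)
        cortex = spec.make_cortex()
        cortex.area_inner[:] = 1.0
        cortex.area_outer[:] = 1.5
        vp = simulate_depth_profiles(cortex, spec, 1)[0]
        for c in CLASSES:
            idx = cortex.atlas.class_indices(c)
            sel = np.isin(cortex.vertex_parcel, idx)
            block = vp[sel]
            np.testing.assert_allclose(block - block[0], 0.0, atol=1e-12)

    def test_identical_class_curves_equalize_similarity(self):
        # all classes share one curve and there is no parcel effect: expected
        # profiles are identical within AND between classes
        curve = {c: (1.2, 0.5, -0.1) for c in CLASSES}
        spec = GenerativeSpec(n_parcels=16, vertices_per_parcel=4, seed=0,
                              hierarchy="class", class_curves=curve,
                              parcel_effect_sd=0.0)
        cortex = spec.make_cortex()
        cortex.area_inner[:] = 1.0
        cortex.area_outer[:] = 2.0
        prof = expected_parcel_profiles(cortex, spec)
        np.testing.assert_allclose(prof - prof[0], 0.0, atol=1e-12)

    def test_continuous_hierarchy_tracks_axis(self):
        spec = GenerativeSpec(n_parcels=100, seed=0, parcel_effect_sd=0.0)
        cortex = spec.make_cortex()
        prof = expected_parcel_profiles(cortex, spec)
        t = hierarchy_position(cortex.atlas)
        # mean intensity decreases from the idiotypic (t=0) to paralimbic end
        r = np.corrcoef(t, prof.mean(axis=1))[0, 1]
        assert r < -0.9

    def test_hierarchy_position_quarters_match_classes(self, cortex100):
        t = hierarchy_position(cortex100.atlas)
        for k, c in enumerate(CLASSES):
            idx = cortex100.atlas.class_indices(c)
            assert np.all((t[idx] > k * 0.25) & (t[idx] < (k + 1) * 0.25))


class TestSimilarityAndCovariance:
    def test_similarity_unit_diagonal_symmetric(self, small_cortex, small_spec):
        S = microstructure_similarity(small_cortex, small_spec)
        np.testing.assert_allclose(np.diag(S), 1.0)
        np.testing.assert_allclose(S, S.T)
        assert np.all(np.abs(S) <= 1.0 + 1e-12)

    def test_functional_covariance_pd(self, small_cortex, small_spec):
        sigma = functional_covariance(small_cortex, small_spec)
        assert np.linalg.eigvalsh(sigma)[0] > 0
        np.testing.assert_allclose(np.diag(sigma), 1.0)

    def test_kappa_one_fc_tracks_similarity(self):
        # kappa=1, noise -> 0: sample FC converges to the similarity pattern
        spec = GenerativeSpec(n_parcels=40, seed=2, kappa=UNIFORM_KAPPA,
                              ts_length=20000, ts_noise_sd=0.0)
        cortex = spec.make_cortex()
        S = microstructure_similarity(cortex, spec)
        ts = simulate_timeseries(cortex, spec, 1)[0]
        r = np.corrcoef(ts.T)
        iu = np.triu_indices(40, 1)
        assert np.corrcoef(r[iu], S[iu])[0, 1] > 0.98

    def test_kappa_zero_coupling_near_zero(self):
        # kappa=0: FC carries no microstructural signal; mean row-wise
        # MPC/FC rank correlation over seeds is within +-0.1 of 0
        means = []
        for seed in range(5):
            spec = GenerativeSpec(n_parcels=40, seed=seed,
                                  kappa={c: 0.0 for c in CLASSES})
            cortex = spec.make_cortex()
            vp = simulate_depth_profiles(cortex, spec, 2)
            mpcs = [mpc_subject(parcel_mean_profiles(p, cortex.vertex_parcel,
                                                     atlas=cortex.atlas))
                    for p in vp]
            mpc = np.mean([m.values for m in mpcs], axis=0)
            ts = simulate_timeseries(cortex, spec, 2)
            fc = np.mean([fc_subject(x).values for x in ts], axis=0)
            means.append(np.nanmean(rowwise_coupling(mpc, fc)))
        assert abs(np.mean(means)) < 0.1


class TestTwinCohort:
    def test_counts_and_structure(self):
        cohort = simulate_twin_cohort(n_mz_pairs=10, n_dz_pairs=5,
                                      n_singletons=7, seed=0)
        z = cohort.pedigree["zygosity"]
        assert (z == "MZ").sum() == 20
        assert (z == "DZ").sum() == 10
        assert (z == "singleton").sum() == 7
        assert len(cohort.pairs("MZ")) == 10
        assert len(cohort.pairs("DZ")) == 5

    def test_mz_share_age_and_sex_dz_share_age(self):
        cohort = simulate_twin_cohort(n_mz_pairs=20, n_dz_pairs=20,
                                      n_singletons=0, seed=1)
        ped = cohort.pedigree
        for i, j in cohort.pairs("MZ"):
            assert ped.loc[i, "age"] == ped.loc[j, "age"]
            assert ped.loc[i, "sex"] == ped.loc[j, "sex"]
        for i, j in cohort.pairs("DZ"):
            assert ped.loc[i, "age"] == ped.loc[j, "age"]

    def test_h2_zero_pair_correlations_near_zero(self):
        cohort = simulate_twin_cohort(n_mz_pairs=500, n_dz_pairs=500,
                                      n_singletons=0, h2_true=0.0,
                                      covariate_betas=(0, 0, 0, 0, 0), seed=2)
        y = cohort.phenotypes.iloc[:, 0].to_numpy()
        mz = np.array(cohort.pairs("MZ"))
        dz = np.array(cohort.pairs("DZ"))
        assert abs(np.corrcoef(y[mz[:, 0]], y[mz[:, 1]])[0, 1]) < 0.1
        assert abs(np.corrcoef(y[dz[:, 0]], y[dz[:, 1]])[0, 1]) < 0.1

    def test_h2_one_mz_correlation_exact(self):
        cohort = simulate_twin_cohort(n_mz_pairs=100, n_dz_pairs=100,
                                      n_singletons=0, h2_true=1.0,
                                      covariate_betas=(0, 0, 0, 0, 0), seed=3)
        y = cohort.phenotypes.iloc[:, 0].to_numpy()
        mz = np.array(cohort.pairs("MZ"))
        np.testing.assert_allclose(y[mz[:, 0]], y[mz[:, 1]], atol=1e-12)
        dz = np.array(cohort.pairs("DZ"))
        r_dz = np.corrcoef(y[dz[:, 0]], y[dz[:, 1]])[0, 1]
        assert abs(r_dz - 0.5) < 0.2

    def test_expected_pair_correlations_h2_half(self):
        # r_MZ = h2, r_DZ = h2/2 in expectation; average over seeds to keep the
        # Monte-Carlo error of the check well below the tolerance
        r_mz, r_dz = [], []
        for seed in range(5):
            cohort = simulate_twin_cohort(n_mz_pairs=500, n_dz_pairs=500,
                                          n_singletons=0, h2_true=0.5,
                                          covariate_betas=(0, 0, 0, 0, 0),
                                          seed=seed)
            y = cohort.phenotypes.iloc[:, 0].to_numpy()
            mz = np.array(cohort.pairs("MZ"))
            dz = np.array(cohort.pairs("DZ"))
            r_mz.append(np.corrcoef(y[mz[:, 0]], y[mz[:, 1]])[0, 1])
            r_dz.append(np.corrcoef(y[dz[:, 0]], y[dz[:, 1]])[0, 1])
        assert np.mean(r_mz) == pytest.approx(0.5, abs=0.07)
        assert np.mean(r_dz) == pytest.approx(0.25, abs=0.07)

    def test_invalid_h2(self):
        with pytest.raises(ValueError):
            simulate_twin_cohort(n_mz_pairs=5, n_dz_pairs=5, n_singletons=0,
                                 h2_true=1.5)

    def test_csv_roundtrip(self, tmp_path):
        cohort = simulate_twin_cohort(n_mz_pairs=4, n_dz_pairs=3, n_singletons=2,
                                      seed=5)
        pp = tmp_path / "ped.csv"
        hp = tmp_path / "phen.csv"
        cohort.to_csv(pp, hp)
        back = TwinCohort.from_csv(pp, hp)
        assert back.n_subjects == cohort.n_subjects
        np.testing.assert_allclose(back.phenotypes.to_numpy(),
                                   cohort.phenotypes.to_numpy())

    def test_validation(self):
        import pandas as pd

        ped = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "family_id": ["f0", "f0", "f0"],
            "zygosity": ["MZ", "MZ", "MZ"],
            "age": [30.0, 30.0, 30.0],
            "sex": [0, 0, 1],
        })
        with pytest.raises(ValueError, match="2 members"):
            TwinCohort(ped, pd.DataFrame(index=range(3)))
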