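import numpy as np
import pytest
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis

from valencepop.geometry import (
    PopulationVectorSet,
    build_population_vectors,
    ensemble_md,
    mahalanobis_distance,
    noise_correlations,
    pca_reduce,
    trial_md_trajectory,
)
from valencepop.preprocessing import ZScoreTensor


def zscore_like(values, per_trial, stimuli=None):
    return ZScoreTensor(np.asarray(values, float), 10.0, 100, per_trial,
                        stimuli=stimuli)


class TestNoiseCorrelations:
    def test_identical_fluctuations_r_one(self, rng):
        base = rng.standard_normal(10)
        resp = np.stack([base + 1.0, base - 2.0])
        nc = noise_correlations(resp, np.zeros(2, int))
        assert nc.coefficients[0] == pytest.approx(1.0)

    def test_sign_flipped_r_minus_one(self, rng):
        base = rng.standard_normal(10)
        resp = np.stack([base, -base])
        nc = noise_correlations(resp, np.zeros(2, int))
        assert nc.coefficients[0] == pytest.approx(-1.0)

    def test_zero_variance_neuron_skipped(self, rng):
        resp = np.vstack([np.ones(10),
                          rng.standard_normal((2, 10))])
        with pytest.warns(UserWarning, match="zero-variance"):
            nc = noise_correlations(resp, np.zeros(3, int))
        assert len(nc.coefficients) == 1  # only the two noisy neurons pair

    def test_cross_mouse_pairs_excluded(self, rng):
        resp = rng.standard_normal((4, 10))
        nc = noise_correlations(resp, np.array([0, 0, 1, 1]))
        assert len(nc.coefficients) == 2
        assert set(nc.per_mouse_mean) == {0, 1}


class TestPopulationVectors:
    def test_timepoint_vectors_shape(self, rng):
        z = zscore_like(rng.standard_normal((3, 230)), per_trial=False)
        pvs = build_population_vectors(z, per="timepoint")
        assert pvs.vectors.shape == (10, 3)

    def test_neuron_permutation_permutes_coordinates(self, rng):
        raw = rng.standard_normal((5, 230))
        perm = np.array([3, 1, 4, 0, 2])
        a = build_population_vectors(zscore_like(raw, False), per="timepoint")
        b = build_population_vectors(zscore_like(raw[perm], False),
                                     per="timepoint")
        assert np.allclose(a.vectors[:, perm], b.vectors)

    def test_trial_vectors_constant_z(self):
        values = np.ones((4, 6, 230))
        pvs = build_population_vectors(zscore_like(values, True),
                                       per="trial")
        assert pvs.vectors.shape == (6, 4)
        assert np.allclose(pvs.vectors, pvs.vectors[0])


class TestPCA:
    def test_rank_one_data_single_component(self, rng):
        direction = rng.standard_normal(8)
        coeffs = rng.standard_normal(30)
        pvs = PopulationVectorSet(np.outer(coeffs, direction),
                                  np.arange(30), "trial")
        _, space = pca_reduce(pvs, 2)
        assert space.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self, rng):
        x = rng.standard_normal((20, 5))
        pvs = PopulationVectorSet(x, np.arange(20), "trial")
        reduced, space = pca_reduce(pvs, 5)
        back = reduced.vectors @ space.components + space.mean
        assert np.allclose(back, x, atol=1e-10)

    def test_explained_variance_nonincreasing(self, rng):
        x = rng.standard_normal((40, 6)) * np.arange(1, 7)
        _, space = pca_reduce(
            PopulationVectorSet(x, np.arange(40), "trial"), 6)
        assert np.all(np.diff(space.explained_variance_ratio) <= 1e-12)

    def test_invalid_k_rejected(self, rng):
        pvs = PopulationVectorSet(rng.standard_normal((4, 3)),
                                  np.arange(4), "trial")
        with pytest.raises(ValueError):
            pca_reduce(pvs, 5)

    def test_out_of_sample_projection_uses_fit_mean(self, rng):
        x = rng.standard_normal((30, 4)) + 5.0
        _, space = pca_reduce(PopulationVectorSet(x, np.arange(30), "trial"), 2)
        assert np.allclose(space.transform(x[:3]),
                           (x[:3] - space.mean) @ space.components.T)


class TestMahalanobis:
    def test_query_at_reference_mean_is_zero(self, rng):
        ref = rng.standard_normal((50, 3))
        assert mahalanobis_distance(ref.mean(axis=0), ref) == pytest.approx(
            0.0, abs=1e-9)

    def test_hand_computed_cross_example(self):
        ref = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], float)
        assert mahalanobis_distance([1, 1], ref) == pytest.approx(np.sqrt(3))

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        # large standard-normal reference so S ~ I; also cross-check the
        # quadratic form against scipy's implementation exactly
        for _ in range(100):
            dim = rng.integers(2, 6)
            ref = rng.standard_normal((4000, dim))
            q = rng.standard_normal(dim) * 3
            md = mahalanobis_distance(q, ref, ridge=0.0)
            cov = np.cov(ref, rowvar=False, ddof=1)
            expect = scipy_mahalanobis(q, ref.mean(axis=0),
                                       np.linalg.inv(cov))
            assert md == pytest.approx(expect, rel=1e-9)
            assert md == pytest.approx(np.linalg.norm(q - ref.mean(axis=0)),
                                       rel=0.15)

    def test_affine_invariance(self, rng):
        ref = rng.standard_normal((60, 4))
        q = rng.standard_normal(4)
        base = mahalanobis_distance(q, ref, ridge=0.0)
        for _ in range(10):
            a = rng.standard_normal((4, 4))
            a += 4 * np.eye(4)  # keep it well-conditioned
            b = rng.standard_normal(4)
            md = mahalanobis_distance(q @ a.T + b, ref @ a.T + b, ridge=0.0)
            assert md == pytest.approx(base, abs=1e-8)

    def test_singular_without_ridge_raises(self):
        ref = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(np.linalg.LinAlgError):
            mahalanobis_distance([0, 0], ref, ridge=0.0)
        # with ridge enabled the distance is finite
        assert np.isfinite(mahalanobis_distance([0, 0], ref, ridge=1e-6))


class TestEnsembleMD:
    def test_identical_sets_zero(self, rng):
        v = rng.standard_normal((10, 3))
        a = PopulationVectorSet(v, np.arange(10), "timepoint")
        b = PopulationVectorSet(v.copy(), np.arange(10), "timepoint")
        assert ensemble_md(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_translation(self, rng):
        v = rng.standard_normal((40, 3))
        a = PopulationVectorSet(v, np.arange(40), "timepoint")
        mds = []
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            b = PopulationVectorSet(v + np.array([delta, 0, 0]),
                                    np.arange(40), "timepoint")
            mds.append(ensemble_md(a, b))
        assert all(x < y for x, y in zip(mds, mds[1:]))

    def test_dimension_mismatch_rejected(self, rng):
        a = PopulationVectorSet(rng.standard_normal((5, 3)), np.arange(5),
                                "timepoint")
        b = PopulationVectorSet(rng.standard_normal((5, 2)), np.arange(5),
                                "timepoint")
        with pytest.raises(ValueError):
            ensemble_md(a, b)

    def test_learning_separates_cs_but_not_us_ensembles(self):
        # paper-mimic synthetic: learning moves CS1/CS2 apart while the
        # innate US1/US2 separation stays put
        from valencepop.pipeline import _ensemble_mds
        from valencepop.synthetic import (
            generate_stage_dataset,
            paper_mimic_config,
        )

        pre = generate_stage_dataset(
            paper_mimic_config("pre", seed=2, n_mice=3,
                               n_neurons_per_mouse=60), "pre")
        post = generate_stage_dataset(
            paper_mimic_config("post", seed=2, n_mice=3,
                               n_neurons_per_mouse=60), "post")
        md_pre = _ensemble_mds(pre.tensor, 2)
        md_post = _ensemble_mds(post.tensor, 2)
        assert md_post["CS1/CS2"] > md_pre["CS1/CS2"]
        assert abs(md_post["US1/US2"] - md_pre["US1/US2"]) < (
            0.5 * md_pre["US1/US2"])


class TestTrialTrajectory:
    def test_reference_mean_trial_near_zero(self, rng):
        x = rng.standard_normal((40, 6))
        x[0] = x[1:11].mean(axis=0)  # plant a trial at the reference mean
        pvs = PopulationVectorSet(x, np.arange(40), "trial")
        # use full-dimensional scores of a 6-dim space reduced to 3: the
        # planted trial is near zero only in the reduced space of the ref
        traj = trial_md_trajectory(pvs, np.arange(1, 11), n_components=3)
        assert traj.distances[0] < np.median(traj.distances)

    def test_one_sd_offset_along_principal_axis(self, rng):
        ref = rng.standard_normal((2000, 3)) * np.array([2.0, 1.0, 0.5])
        q = ref.mean(axis=0) + np.array([2.0, 0.0, 0.0])  # +1 sample SD
        assert mahalanobis_distance(q, ref) == pytest.approx(1.0, abs=0.05)

    def test_remapped_trials_farther_than_reference(self):
        from valencepop.synthetic import GeneratorConfig, generate_reversal_dataset
        from valencepop.preprocessing import zscore_per_trial
        from valencepop.geometry import build_population_vectors

        cfg = GeneratorConfig(n_mice=1, n_neurons_per_mouse=60, seed=4,
                              shared_noise_fraction=0.05)
        ds = generate_reversal_dataset(cfg, "punishment_to_reward")
        z = zscore_per_trial(ds.tensor)
        pvs = build_population_vectors(z, per="trial")
        traj = trial_md_trajectory(pvs, np.arange(10))
        assert traj.distances[-20:].mean() > traj.distances[:10].mean()
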