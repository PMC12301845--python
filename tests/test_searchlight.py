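"""Searchlight RSA, group inference and reward decoding."""

import itertools

import numpy as np
import pytest

from rctrsa import rdm, searchlight, simulate, task
from rctrsa.searchlight import (
    ball_offsets,
    group_inference,
    make_spheres,
    reward_classification_map,
    signed_rank_null_tail,
    signed_rank_p,
    smooth_map,
    subject_rsa_map,
)


class TestSpheres:
    def test_interior_sphere_has_33_voxels(self):
        # brute-force count of integer offsets within the whole-voxel
        # radius floor(6 / 2.5) = 2
        r = int(6.0 // 2.5)
        count = sum(
            1
            for d in itertools.product(range(-r, r + 1), repeat=3)
            if np.sqrt(sum(x**2 for x in d)) <= r
        )
        assert count == 33
        assert len(ball_offsets(2.5, 6.0)) == 33

    def test_isolated_voxel_gives_singleton_sphere(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        spheres = make_spheres(mask)
        assert len(spheres) == 1
        assert spheres[0].members.shape == (1, 3)

    def test_all_members_in_mask_and_center_included(self):
        rng = np.random.default_rng(0)
        mask = rng.random((6, 7, 6)) < 0.6
        mask[0, 0, 0] = True
        for sphere in make_spheres(mask):
            members = {tuple(m) for m in sphere.members}
            assert sphere.center in members
            for m in members:
                assert mask[m]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            make_spheres(np.zeros((3, 3, 3), dtype=bool))


@pytest.fixture(scope="module")
def random_betas():
    rng = np.random.default_rng(1)
    return rng.standard_normal((4, 24, 8, 8, 8))


@pytest.fixture(scope="module")
def random_model():
    rng = np.random.default_rng(2)
    return rdm.euclidean_rdm(rng.standard_normal((24, 12)))


class TestSubjectMap:
    def test_matches_explicit_sphere_loop(self, random_betas, random_model):
        out = subject_rsa_map(random_betas, random_model, fwhm=0)
        r_map = out.stages["r"]
        grid = random_betas.shape[2:]
        flat = random_betas.reshape(4, 24, -1)
        rng = np.random.default_rng(3)
        spheres = make_spheres(np.ones(grid, dtype=bool))
        for s in rng.choice(len(spheres), size=20, replace=False):
            sphere = spheres[s]
            if len(sphere.members) < searchlight.MIN_SPHERE_VOXELS:
                assert np.isnan(r_map[sphere.center])
                continue
            lin = np.ravel_multi_index(sphere.members.T, grid)
            sphere_rdm = rdm.cv_euclidean_rdm(flat[:, :, lin])
            expected = rdm.spearman(sphere_rdm.vector(), random_model.vector())
            assert r_map[sphere.center] == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_monotone_model_transform(self, random_betas, random_model):
        a = subject_rsa_map(random_betas, random_model)
        warped = rdm.RDM(np.exp(random_model.matrix), random_model.labels)
        b = subject_rsa_map(random_betas, warped)
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_invariant_to_constant_beta_shift(self, random_betas, random_model):
        a = subject_rsa_map(random_betas, random_model)
        b = subject_rsa_map(random_betas + 5.0, random_model)
        assert np.allclose(a.values, b.values, atol=1e-8, equal_nan=True)

    def test_zmap_standardized_before_smoothing(self, random_betas, random_model):
        out = subject_rsa_map(random_betas, random_model)
        z = out.stages["z"]
        vals = z[np.isfinite(z)]
        assert vals.mean() == pytest.approx(0.0, abs=1e-10)
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_noise_free_planted_subject_peaks_in_roi(self, noise_free_subject,
                                                     model_rdms):
        dataset, betas, target = noise_free_subject
        out = subject_rsa_map(betas, target, fwhm=0)
        roi_mask = dataset.truth["plant"].roi_mask
        center = tuple(np.array(np.where(roi_mask)).mean(axis=1).astype(int))
        assert out.stages["r"][center] > 0.9
        z = out.stages["z"]
        peak = np.unravel_index(np.nanargmax(z), z.shape)
        assert roi_mask[peak]

    def test_smoothing_preserves_constant_maps(self):
        values = np.full((6, 6, 6), 2.5)
        out = smooth_map(values, fwhm=6.0, voxel_size=2.5)
        assert np.allclose(out, 2.5)


class TestSignedRank:
    def test_exact_p_for_six_positive_subjects(self):
        # oracle: enumerate all 2^6 sign patterns of the rank sum
        n = 6
        ranks = np.arange(1, n + 1)
        null = []
        for signs in itertools.product([0, 1], repeat=n):
            null.append((ranks * signs).sum())
        null = np.array(null)
        w_obs = ranks.sum()
        expected = (null >= w_obs).mean()
        assert expected == pytest.approx(1 / 64)
        assert signed_rank_p(np.abs(np.random.default_rng(0).standard_normal(6)) + 0.1
                             ) == pytest.approx(1 / 64)

    def test_tail_is_a_valid_survival_function(self):
        tail = signed_rank_null_tail(8)
        assert tail[0] == pytest.approx(1.0)
        assert (np.diff(tail) <= 1e-12).all()
        assert tail[-1] == pytest.approx(1 / 2**8)


@pytest.fixture(scope="module")
def null_maps():
    # 12 subjects: the exact voxel threshold p<0.001 is attainable
    rng = np.random.default_rng(4)
    return [rng.standard_normal((10, 10, 10)) for _ in range(12)]


class TestGroupInference:
    def test_null_group_yields_no_significant_cluster(self, null_maps):
        _, clusters = group_inference(null_maps, n_perm=300, seed=0)
        assert not clusters["significant"].any()

    def test_one_sidedness_under_negation(self):
        # a consistent positive blob is detected; its negation is not
        rng = np.random.default_rng(11)
        maps = []
        for _ in range(12):
            vol = rng.standard_normal((10, 10, 10))
            vol[3:6, 3:6, 3:6] += 2.0
            maps.append(vol)
        _, clusters = group_inference(maps, n_perm=300, seed=0)
        assert clusters["significant"].any()
        _, neg_clusters = group_inference([-m for m in maps], n_perm=300, seed=0)
        assert not neg_clusters["significant"].any()

    def test_planted_cohort_recovers_single_roi_cluster(self, cohort10,
                                                        cohort10_analysis):
        clusters = cohort10_analysis["clusters"]
        significant = clusters[clusters["significant"]]
        assert len(significant) == 1
        roi_mask = cohort10[0].truth["plant"].roi_mask
        peak = significant.iloc[0]
        assert roi_mask[int(peak.peak_x), int(peak.peak_y), int(peak.peak_z)]

    def test_too_few_subjects_rejected(self, null_maps):
        with pytest.raises(ValueError):
            group_inference(null_maps[:3])

    def test_voxelwise_null_calibration(self):
        # 20 pure-noise subject maps: the supra-threshold fraction at
        # p<0.001 stays at the nominal order of magnitude
        rng = np.random.default_rng(5)
        stack = rng.standard_normal((20, 12, 12, 12))
        ranks = np.empty_like(stack)
        from scipy.stats import rankdata

        flat = stack.reshape(20, -1)
        ranks = rankdata(np.abs(flat), axis=0)
        W = (ranks * (flat > 0)).sum(axis=0)
        tail = signed_rank_null_tail(20)
        p = tail[np.round(W).astype(int)]
        frac = (p < 0.001).mean()
        assert frac < 0.004
        z = flat.mean()
        assert abs(z) < 0.05


class TestRewardDecoding:
    def test_hand_traced_two_voxel_fixture(self):
        # 2 runs, 2 states (one rewarded), 1-voxel mask: centroid of the
        # training run classifies the held-out run
        betas = np.zeros((2, 2, 1, 1, 1))
        betas[0, 0], betas[0, 1] = 1.0, -1.0
        betas[1, 0], betas[1, 1] = 0.8, -0.6
        labels = np.array([True, False])
        out = reward_classification_map(betas, labels, min_voxels=1)
        # every test pattern is nearer its own class centroid in both folds
        assert out.values[0, 0, 0] == pytest.approx(1.0)

    def test_chance_level_on_label_shuffled_noise(self):
        rng = np.random.default_rng(6)
        betas = rng.standard_normal((4, 24, 8, 8, 8))
        labels = np.zeros(24, dtype=bool)
        labels[rng.choice(24, size=12, replace=False)] = True
        out = reward_classification_map(betas, labels)
        vals = out.values[np.isfinite(out.values)]
        assert abs(vals.mean() - 0.5) < 0.05

    def test_perfect_accuracy_on_separable_patterns(self):
        grid = (8, 8, 8)
        rng = np.random.default_rng(7)
        signal = rng.standard_normal((1, 24, *grid)) * 0.01
        condition = np.zeros((24, *grid))
        condition[:12] = 1.0
        condition[12:] = -1.0
        betas = np.repeat(signal, 4, axis=0) + condition[None]
        labels = np.arange(24) < 12
        out = reward_classification_map(betas, labels)
        vals = out.values[np.isfinite(out.values)]
        assert np.allclose(vals, 1.0)

    def test_single_class_rejected(self):
        betas = np.zeros((2, 4, 3, 3, 3))
        with pytest.raises(ValueError):
            reward_classification_map(betas, np.ones(4, dtype=bool))
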