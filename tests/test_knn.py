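"""Voxel k-NN classifier: features, fitting, exact neighbor probabilities."""

import numpy as np
import pytest

from wmhresample import (
    FeatureConfig,
    InputError,
    ParameterError,
    PhantomParams,
    SubjectImage,
    TrainingPointPolicy,
    binarize,
    extract_features,
    fit,
    knn_lesion_fraction,
    load_classifier,
    predict_probability,
    save_classifier,
)


def brute_force_fraction(ref, labels, query, k):
    """Independent oracle: full distance matrix + stable sort."""
    d = ((query[:, None, :].astype(np.float64) - ref[None, :, :].astype(np.float64)) ** 2).sum(
        axis=2
    )
    order = np.argsort(d, axis=1, kind="stable")
    return labels[order[:, :k]].mean(axis=1).astype(np.float32)


def make_subject(flair, t1, brain, manual, voxel_dims=(1.0, 1.0, 1.0)):
    return SubjectImage(
        participant_id="t", timepoint="BL",
        flair=flair, t1=t1, brain_mask=brain, manual_mask=manual,
        voxel_dims=voxel_dims,
    )


@pytest.fixture
def flat_subject():
    rng = np.random.default_rng(0)
    shape = (6, 6, 6)
    brain = np.ones(shape, dtype=bool)
    manual = np.zeros(shape, dtype=bool)
    manual[2:4, 2:4, 2:4] = True
    flair = rng.normal(100, 10, shape)
    flair[manual] += 50
    t1 = rng.normal(120, 10, shape)
    return make_subject(flair, t1, brain, manual)


class TestExtractFeatures:
    def test_arity_two_modalities_plus_coords(self, flat_subject):
        feats, idx = extract_features(flat_subject, FeatureConfig())
        assert feats.shape == (6 * 6 * 6, 5)
        assert idx.shape == (6 * 6 * 6, 3)

    def test_zero_spatial_weight_kills_coordinates(self, flat_subject):
        feats, _ = extract_features(flat_subject, FeatureConfig(spatial_weight=0.0))
        assert np.all(feats[:, 2:] == 0.0)

    def test_intensities_standardized_within_mask(self, flat_subject):
        feats, _ = extract_features(flat_subject, FeatureConfig())
        assert feats[:, 0].mean() == pytest.approx(0.0, abs=1e-5)
        assert feats[:, 0].std() == pytest.approx(1.0, abs=1e-4)

    def test_constant_image_guard(self, flat_subject):
        s = make_subject(
            np.full_like(flat_subject.flair, 7.0),
            flat_subject.t1,
            flat_subject.brain_mask,
            flat_subject.manual_mask,
        )
        feats, _ = extract_features(s, FeatureConfig())
        assert np.all(feats[:, 0] == 0.0)

    def test_empty_mask_rejected(self, flat_subject):
        s = make_subject(
            flat_subject.flair, flat_subject.t1,
            np.zeros_like(flat_subject.brain_mask),
            np.zeros_like(flat_subject.manual_mask),
        )
        with pytest.raises(InputError):
            extract_features(s, FeatureConfig())


class TestFit:
    def test_caps_bind_exactly(self, flat_subject):
        policy = TrainingPointPolicy(max_lesion_points=5, max_nonlesion_points=50)
        clf = fit([flat_subject], policy, FeatureConfig(), k=3)
        assert len(clf.features) == 55
        assert clf.labels.sum() == 5

    def test_cap_not_binding_keeps_all(self, flat_subject):
        policy = TrainingPointPolicy(max_lesion_points=2000, max_nonlesion_points=10000)
        clf = fit([flat_subject], policy, FeatureConfig(), k=3)
        assert clf.labels.sum() == int(flat_subject.manual_mask.sum())

    def test_degenerate_all_zero_masks(self, flat_subject):
        s = make_subject(
            flat_subject.flair, flat_subject.t1,
            flat_subject.brain_mask, np.zeros_like(flat_subject.manual_mask),
        )
        with pytest.warns(UserWarning, match="no lesion voxels"):
            clf = fit([s], TrainingPointPolicy(), FeatureConfig(), k=3)
        assert clf.is_degenerate
        prob = predict_probability(clf, flat_subject)
        assert np.all(prob.values == 0.0)

    def test_save_load_round_trip(self, flat_subject, tmp_path):
        clf = fit([flat_subject], TrainingPointPolicy(5, 50), FeatureConfig(), k=3,
                  draw_id="n002_r001")
        path = save_classifier(clf, tmp_path / "model.npz")
        back = load_classifier(path)
        assert np.array_equal(back.features, clf.features)
        assert np.array_equal(back.labels, clf.labels)
        assert back.k == clf.k and back.draw_id == clf.draw_id
        assert back.config == clf.config
        assert back.normalization_stats == clf.normalization_stats


class TestKnnProbabilities:
    def test_matches_brute_force_oracle_small_instances(self):
        """Exact equivalence with a distance-sort oracle on 100 random
        <=100-voxel instances."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_ref = int(rng.integers(5, 100))
            n_q = int(rng.integers(1, 100))
            dim = int(rng.integers(2, 6))
            k = int(rng.integers(1, n_ref + 1))
            ref = rng.normal(size=(n_ref, dim)).astype(np.float32)
            labels = (rng.random(n_ref) < 0.3).astype(np.uint8)
            query = rng.normal(size=(n_q, dim)).astype(np.float32)
            got = knn_lesion_fraction(ref, labels, query, k)
            assert np.array_equal(got, brute_force_fraction(ref, labels, query, k))

    def test_matches_oracle_on_large_screened_instance(self):
        """The p=0 screening path must agree with the oracle too."""
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(600, 5)).astype(np.float32)
        labels = (rng.random(600) < 0.15).astype(np.uint8)
        query = rng.normal(size=(2000, 5)).astype(np.float32)
        got = knn_lesion_fraction(ref, labels, query, 40)
        assert np.array_equal(got, brute_force_fraction(ref, labels, query, 40))

    def test_probabilities_are_multiples_of_one_over_k(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(size=(50, 5)).astype(np.float32)
        labels = (rng.random(50) < 0.4).astype(np.uint8)
        q = rng.normal(size=(40, 5)).astype(np.float32)
        p = knn_lesion_fraction(ref, labels, q, 7)
        assert np.allclose(np.round(p * 7), p * 7, atol=1e-5)
        assert np.all((p >= 0) & (p <= 1))

    def test_all_lesion_reference_gives_one(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(20, 5)).astype(np.float32)
        q = rng.normal(size=(9, 5)).astype(np.float32)
        p = knn_lesion_fraction(ref, np.ones(20, dtype=np.uint8), q, 5)
        assert np.all(p == 1.0)

    def test_duplicated_query_point_k1(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(size=(10, 5)).astype(np.float32)
        labels = np.zeros(10, dtype=np.uint8)
        labels[3] = 1
        p = knn_lesion_fraction(ref, labels, ref[[3]], 1)
        assert p[0] == 1.0

    def test_tie_broken_by_stable_reference_order(self):
        # four references equidistant from the origin query; k=2 must take
        # the two with the lowest indices
        ref = np.array(
            [[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=np.float32
        )
        labels = np.array([1, 1, 0, 0], dtype=np.uint8)
        q = np.zeros((1, 2), dtype=np.float32)
        assert knn_lesion_fraction(ref, labels, q, 2)[0] == 1.0
        labels2 = np.array([0, 0, 1, 1], dtype=np.uint8)
        assert knn_lesion_fraction(ref, labels2, q, 2)[0] == 0.0

    def test_invalid_k_rejected(self):
        ref = np.zeros((5, 2), dtype=np.float32)
        labels = np.zeros(5, dtype=np.uint8)
        with pytest.raises(ParameterError):
            knn_lesion_fraction(ref, labels, ref, 6)


class TestBinarize:
    def test_threshold_boundary_inclusive(self):
        vals = np.array([0.0, 0.5, 0.8])
        assert list(binarize(vals, 0.8)) == [False, False, True]
        assert list(binarize(vals, 0.5)) == [False, True, True]

    def test_zero_threshold_excludes_zero_probability(self):
        vals = np.array([0.0, 0.1, 0.9])
        assert list(binarize(vals, 0.0)) == [False, True, True]

    def test_nested_masks_over_threshold_grid(self):
        rng = np.random.default_rng(9)
        vals = rng.random((8, 8, 8)).astype(np.float32)
        grid = np.round(np.arange(0.0, 1.01, 0.1), 1)
        prev = None
        for t in grid[::-1]:  # descending t: masks must grow
            mask = binarize(vals, float(t))
            if prev is not None:
                assert np.all(mask[prev])  # prev (higher t) subset of mask
            prev = mask

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ParameterError):
            binarize(np.zeros((2, 2, 2)), 1.5)


class TestSanityRecovery:
    def test_noiseless_phantom_recovered_exactly(self):
        """With well-separated tissue intensities, no noise and no spatial
        features, the predicted mask at t=0.8 equals the ground truth."""
        from wmhresample.phantom import generate_subject

        params = PhantomParams(
            grid_shape=(20, 20, 20), voxel_dims=(2.0, 2.0, 2.0),
            n_paired=1, n_external=0, noise_sd=0.0,
            tissue_sds={k: (0.0, 0.0) for k in ("background", "csf", "wm", "gm", "lesion")},
        )
        s = generate_subject(params, 0.3, "p", "BL", np.random.default_rng(10))
        config = FeatureConfig(spatial_weight=0.0)
        clf = fit([s], TrainingPointPolicy(), config, k=10)
        prob = predict_probability(clf, s)
        predicted = binarize(prob, 0.8)
        assert np.array_equal(predicted, s.manual_mask)

    def test_probability_zero_outside_brain_mask(self, flat_subject):
        brain = flat_subject.brain_mask.copy()
        brain[0] = False
        s = make_subject(
            flat_subject.flair, flat_subject.t1, brain,
            flat_subject.manual_mask & brain,
        )
        clf = fit([s], TrainingPointPolicy(5, 50), FeatureConfig(), k=3)
        prob = predict_probability(clf, s)
        assert np.all(prob.values[~brain] == 0.0)
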