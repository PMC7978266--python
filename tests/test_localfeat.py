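"""FAST/orientation oracles, ORB detection, vocabularies and BoVW encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from leafsense.errors import ConfigError, VocabularyError
from leafsense.localfeat import (
    FAST_CIRCLE,
    LOCAL_FEATURE_NAMES,
    VisualVocabulary,
    build_vocabulary,
    detect_orb,
    encode_bow,
    extract_local_features,
    fast_corner_test,
    intensity_centroid_orientation,
)
from leafsense.segment import ChannelStack, ForegroundMask
from leafsense.synthesize import generate_leaf_image

from oracles import brute_fast, brute_nearest_centroid


def _full_mask(shape):
    return ForegroundMask(np.ones(shape, dtype=bool), 128)


class TestFastCornerTest:
    def test_uniform_patch_is_not_a_corner(self):
        assert not fast_corner_test(np.full((7, 7), 10.0), (3, 3), t=5)

    def test_bright_contiguous_arc_detected(self):
        img = np.full((7, 7), 10.0)
        for dr, dc in FAST_CIRCLE[:12]:
            img[3 + dr, 3 + dc] = 100.0
        assert fast_corner_test(img, (3, 3), t=20)
        assert brute_fast(img, (3, 3), 20)

    def test_dark_arc_symmetry(self):
        img = np.full((7, 7), 100.0)
        for dr, dc in FAST_CIRCLE[:12]:
            img[3 + dr, 3 + dc] = 10.0
        assert fast_corner_test(img, (3, 3), t=20)

    def test_out_of_bounds_center_rejected(self):
        with pytest.raises(ConfigError):
            fast_corner_test(np.zeros((7, 7)), (1, 3), t=5)

    @settings(max_examples=200, deadline=None)
    @given(arrays(np.uint8, (7, 7),
                  elements=st.integers(min_value=0, max_value=255)),
           st.integers(min_value=0, max_value=60),
           st.integers(min_value=6, max_value=12))
    def test_matches_brute_force_arc_enumeration(self, patch, t, n_arc):
        got = fast_corner_test(patch.astype(float), (3, 3), t, n_arc)
        assert got == brute_fast(patch, (3, 3), t, n_arc)


class TestIntensityCentroid:
    def test_radially_symmetric_patch_is_degenerate(self):
        yy, xx = np.mgrid[0:31, 0:31]
        patch = np.exp(-((yy - 15) ** 2 + (xx - 15) ** 2) / 50.0)
        res = intensity_centroid_orientation(patch)
        assert res.degenerate and res.angle == 0.0

    def test_mass_along_positive_x(self):
        patch = np.zeros((31, 31))
        patch[15, 25] = 5.0
        res = intensity_centroid_orientation(patch)
        assert res.angle == pytest.approx(0.0, abs=1e-9)

    def test_mass_along_positive_y(self):
        patch = np.zeros((31, 31))
        patch[25, 15] = 5.0
        res = intensity_centroid_orientation(patch)
        assert res.angle == pytest.approx(90.0, abs=1e-9)

    def test_quarter_turn_rotates_angle_by_90(self, rng):
        patch = rng.random((31, 31))
        patch[5:12, 20:27] += 3.0  # asymmetric mass
        a1 = intensity_centroid_orientation(patch).angle
        a2 = intensity_centroid_orientation(np.rot90(patch, k=3)).angle
        delta = (a2 - a1) % 360.0
        assert abs(delta - 90.0) <= 2.0


class TestDetectOrb:
    def test_constant_raster_has_no_corners(self):
        kps, desc = detect_orb(np.full((120, 100), 50.0), _full_mask((120, 100)))
        assert kps == [] and desc.shape == (0, 256)

    def test_small_image_returns_empty(self):
        kps, desc = detect_orb(np.zeros((20, 20)), _full_mask((20, 20)))
        assert kps == []

    def test_keypoints_inside_mask_and_descriptors_binary(self, small_cfg, rng):
        img, mask = generate_leaf_image(0.1, small_cfg, rng)
        gray = img.astype(float) @ np.array([0.299, 0.587, 0.114])
        fm = ForegroundMask(mask, 128)
        kps, desc = detect_orb(gray, fm)
        assert len(kps) == desc.shape[0] > 0
        assert set(np.unique(desc)) <= {0, 1}
        for kp in kps:
            r, c = int(round(kp.y)), int(round(kp.x))
            assert mask[r, c]
            assert 0.0 <= kp.angle < 360.0
            assert kp.octave >= 0

    def test_wilted_leaf_has_more_keypoints_than_fresh(self, small_cfg):
        # texture grows with wilt: paired comparison over 20 seeded pairs
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            wilt_img, wilt_m = generate_leaf_image(0.0, small_cfg, rng)
            rng = np.random.default_rng(1000 + seed)
            fresh_img, fresh_m = generate_leaf_image(1.0, small_cfg, rng)
            luma = np.array([0.299, 0.587, 0.114])
            n_wilt = len(detect_orb(wilt_img.astype(float) @ luma,
                                    ForegroundMask(wilt_m, 128))[0])
            n_fresh = len(detect_orb(fresh_img.astype(float) @ luma,
                                     ForegroundMask(fresh_m, 128))[0])
            wins += n_wilt > n_fresh
        assert wins == 20


def _random_descriptors(rng, n):
    return rng.integers(0, 2, size=(n, 256)).astype(np.uint8)


class TestVocabulary:
    def test_planted_point_masses_recovered(self, rng):
        protos = _random_descriptors(rng, 20)
        pool = np.repeat(protos, 30, axis=0)
        pools = [pool] * 10
        vocabs = build_vocabulary(pools, k=20, km_seed=1)
        assert len(vocabs) == 10
        for v in vocabs:
            assert v.centroids.shape == (20, 256)
            assert v.inertia == pytest.approx(0.0, abs=1e-6)
            # canonical ordering: recovered centroids = sorted prototypes
            expected = protos[np.lexsort(protos.T[::-1].astype(float))]
            np.testing.assert_allclose(v.centroids, expected, atol=1e-9)

    def test_k1_closed_form_is_coordinatewise_mean(self, rng):
        pool = _random_descriptors(rng, 50)
        vocab = build_vocabulary([pool] * 10, k=1, km_seed=0)[0]
        np.testing.assert_allclose(vocab.centroids[0], pool.mean(axis=0),
                                   atol=1e-9)

    def test_too_few_descriptors_rejected_with_advice(self, rng):
        pools = [_random_descriptors(rng, 5)] * 10
        with pytest.raises(VocabularyError, match="larger training set"):
            build_vocabulary(pools, k=20)

    def test_seeded_determinism(self, rng):
        pools = [_random_descriptors(rng, 200) for _ in range(10)]
        v1 = build_vocabulary(pools, km_seed=42)
        v2 = build_vocabulary(pools, km_seed=42)
        for a, b in zip(v1, v2):
            np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_roundtrip_serialization(self, rng):
        v = build_vocabulary([_random_descriptors(rng, 60)] * 10, km_seed=0)[0]
        v2 = VisualVocabulary.from_dict(v.to_dict())
        np.testing.assert_array_equal(v.centroids, v2.centroids)


class TestEncodeBow:
    def _vocab(self, rng, k=20):
        return VisualVocabulary(0, rng.random((k, 256)), 0, 0.0)

    def test_empty_descriptor_list_gives_zero_histogram(self, rng):
        hist = encode_bow(np.zeros((0, 256)), self._vocab(rng))
        assert hist.shape == (20,) and (hist == 0).all()

    def test_known_assignment_counts(self):
        cents = np.zeros((20, 256))
        cents[1, 0] = 1.0  # centroid 1 differs in bit 0
        vocab = VisualVocabulary(0, cents, 0, 0.0)
        d = np.zeros((3, 256))
        d[2, 0] = 1.0  # third descriptor nearest centroid 1
        hist = encode_bow(d, vocab)
        # first two descriptors tie across centroids 0 and 2..19 -> lowest index
        assert hist[0] == 2 and hist[1] == 1 and hist.sum() == 3

    def test_partition_property(self, rng):
        vocab = self._vocab(rng)
        d = _random_descriptors(rng, 137)
        assert encode_bow(d, vocab).sum() == 137

    def test_matches_exhaustive_nearest_centroid(self, rng):
        vocab = self._vocab(rng)
        d = _random_descriptors(rng, 300)
        hist = encode_bow(d, vocab)
        assign = brute_nearest_centroid(d, vocab.centroids)
        np.testing.assert_array_equal(hist, np.bincount(assign, minlength=20))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(VocabularyError):
            encode_bow(np.zeros((3, 128)), self._vocab(rng))


class TestExtractLocalFeatures:
    def test_textureless_leaf_gives_all_zero_histograms(self, rng):
        vocabs = [VisualVocabulary(c, rng.random((20, 256)), 0, 0.0)
                  for c in range(10)]
        stack = ChannelStack(np.full((10, 80, 80), 40.0))
        m = np.zeros((80, 80), dtype=bool)
        m[20:60, 20:60] = True
        lfv = extract_local_features(stack, ForegroundMask(m, 128), vocabs)
        assert lfv.values.shape == (200,)
        assert (lfv.values == 0).all()
        assert len(LOCAL_FEATURE_NAMES) == 200

    def test_bin_sums_equal_keypoint_counts(self, small_cfg, rng):
        from leafsense.segment import (
            LeafImage, decompose_channels, make_foreground_mask,
            otsu_threshold, to_grayscale,
        )

        img, _ = generate_leaf_image(0.1, small_cfg, rng)
        li = LeafImage(img)
        gray = to_grayscale(li)
        fm = make_foreground_mask(gray, otsu_threshold(gray).threshold)
        stack = decompose_channels(li, fm)
        pools = []
        for c in range(10):
            _, d = detect_orb(stack.data[c], fm, channel_index=c)
            pools.append(d if d.size else np.zeros((0, 256), np.uint8))
        pooled = [p if len(p) >= 20 else _random_descriptors(rng, 40)
                  for p in pools]
        vocabs = build_vocabulary(pooled, km_seed=0)
        lfv = extract_local_features(stack, fm, vocabs)
        for c in range(10):
            assert lfv.values[20 * c: 20 * (c + 1)].sum() == \
                lfv.n_keypoints_per_channel[c]
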