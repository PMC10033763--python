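"""Observation preprocessing, noise, combination, synthesis and caching."""

import numpy as np
import pytest

from navrl.observations import (
    NoiseSpec,
    add_noise,
    build_offline_cache,
    combine_observations,
    flatten_observation,
    pose_observation,
    preprocess_image,
    synthesize_state_images,
)


class TestPreprocess:
    def test_uint8_normalization(self):
        img = np.full((4, 4), 255, dtype=np.uint8)
        out = preprocess_image(img, 4, 4)
        assert np.allclose(out, 1.0)

    def test_already_target_size_only_rescaled(self):
        img = np.full((3, 3), 128, dtype=np.uint8)
        out = preprocess_image(img, 3, 3)
        assert out.shape == (3, 3) and np.allclose(out, 128 / 255)

    def test_area_downscale_is_block_mean(self, rng):
        """Integer-factor downscaling equals the brute-force 2x2 block mean."""
        img = rng.uniform(0, 1, (4, 4))
        out = preprocess_image(img, 2, 2)
        expected = np.array([[img[:2, :2].mean(), img[:2, 2:].mean()],
                             [img[2:, :2].mean(), img[2:, 2:].mean()]])
        assert np.allclose(out, expected)

    def test_output_range_and_errors(self, rng):
        out = preprocess_image(rng.uniform(0, 1, (7, 5, 3)), 3, 4)
        assert out.shape == (3, 4, 3) and out.min() >= 0 and out.max() <= 1
        with pytest.raises(ValueError):
            preprocess_image(np.ones((4, 4)), 0, 2)


class TestNoise:
    def test_sigma_zero_identity(self, rng):
        obs = np.linspace(0, 1, 10)
        assert np.array_equal(add_noise(obs, NoiseSpec(sigma=0.0), rng), obs)

    def test_mean_shift_within_clt_bound(self, rng):
        """Unclipped noise has near-zero mean: |mean| < 3 sigma / sqrt(n)."""
        obs = np.full(10_000, 0.5)
        sigma = 0.1
        noisy = add_noise(obs, NoiseSpec(sigma=sigma, clip=False), rng)
        assert abs((noisy - obs).mean()) < 3 * sigma / np.sqrt(obs.size)

    def test_clipping_keeps_unit_range(self, rng):
        noisy = add_noise(np.ones(1000), NoiseSpec(sigma=0.5, clip=True), rng)
        assert noisy.min() >= 0 and noisy.max() <= 1

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(sigma=-0.1)


class TestCombine:
    def test_single_and_multi_entry(self):
        img = np.zeros((2, 2))
        pose = np.array([1.0, 2.0, 0.0])
        single = combine_observations([("vision", img)])
        assert np.array_equal(single["vision"], img)
        multi = combine_observations([("vision", img), ("pose", pose)])
        assert set(multi) == {"vision", "pose"}
        assert np.array_equal(multi["pose"], pose)
        assert flatten_observation(multi).shape == (7,)

    def test_duplicate_key_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            combine_observations([("a", np.zeros(2)), ("a", np.ones(2))])


class TestPose:
    def test_passthrough_and_wrap(self):
        assert np.allclose(pose_observation((1, 2, 90), degrees=True), (1, 2, 90))
        assert np.allclose(pose_observation((0, 0, 370), degrees=True), (0, 0, 10))
        assert np.allclose(pose_observation((0, 0, 2 * np.pi + 0.1))[2], 0.1)


class TestSynthesizedImages:
    def test_deterministic_and_distinct(self):
        a = synthesize_state_images(8, (8, 8), seed=3, n_headings=2)
        b = synthesize_state_images(8, (8, 8), seed=3, n_headings=2)
        hashes = set()
        for s in range(8):
            for hd in range(2):
                assert np.array_equal(a.get(s, hd), b.get(s, hd))
                img = a.get(s, hd)
                assert img.min() >= 0 and img.max() <= 1
                hashes.add(img.tobytes())
        assert len(hashes) == 16  # all (state, heading) images pairwise distinct


class TestOfflineCache:
    def test_transparent_and_counted(self):
        calls = []

        def render(s, hd):
            calls.append((s, hd))
            return np.full((2, 2), s + 0.1 * hd)

        cache = build_offline_cache(render, states=range(3), headings=(0, 1))
        assert len(cache) == 6 and len(calls) == 6
        for s in range(3):
            for hd in (0, 1):
                assert np.array_equal(cache.query(s, hd), render(s, hd))
        # queries served from memory: one render per entry during the session
        assert cache.render_calls == 6

    def test_missing_policies(self):
        cache = build_offline_cache(lambda s, h: np.zeros(1), states=[0], headings=[0])
        with pytest.raises(KeyError):
            cache.query(5, 0)
        lazy = build_offline_cache(lambda s, h: np.full(1, s), states=[0],
                                   headings=[0], on_missing="render")
        assert lazy.query(5, 0)[0] == 5
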