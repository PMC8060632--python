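"""G−R index computation, thresholding and canopy-cover extraction."""

import numpy as np
import pytest
from PIL import Image

from wheatcc import (
    ImageSceneConfig, auto_threshold, cc_from_image_file, cc_table,
    compute_gr_index, generate_canopy_image, segment_canopy,
)


def _uniform(r, g, b, shape=(4, 5)):
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img


class TestGrIndex:
    @pytest.mark.parametrize(
        "rgb, expected",
        [((10, 200, 0), 190),      # direct subtraction
         ((200, 10, 255), -190),   # blue ignored, negative allowed
         ((128, 128, 128), 0)],    # gray maps to zero
    )
    def test_pixel_values(self, rgb, expected):
        gr = compute_gr_index(_uniform(*rgb))
        assert gr.shape == (4, 5)
        assert (gr == expected).all()

    def test_no_clamping_and_signed_dtype(self):
        gr = compute_gr_index(_uniform(0, 255, 0))
        assert gr.dtype == np.int16
        assert (gr == 255).all()

    def test_rejects_non_rgb_modes(self):
        for mode in ("L", "P"):
            im = Image.new(mode, (3, 3))
            with pytest.raises(ValueError, match=mode):
                compute_gr_index(im)

    def test_alpha_channel_is_dropped(self):
        im = Image.new("RGBA", (3, 3), (10, 200, 0, 7))
        assert (compute_gr_index(im) == 190).all()


class TestSegmentation:
    def test_all_above_threshold(self):
        gr = np.full((10, 10), 50, dtype=np.int16)
        assert segment_canopy(gr, 0).cc == 1.0

    def test_boundary_pixels_are_background(self):
        gr = np.zeros((10, 10), dtype=np.int16)
        assert segment_canopy(gr, 0).cc == 0.0

    def test_counts_match_brute_force(self, rng):
        # 3,000 of 10,000 pixels strictly above the threshold
        gr = np.full(10_000, -5, dtype=np.int16)
        above = rng.choice(10_000, size=3_000, replace=False)
        gr[above] = 40
        seg = segment_canopy(gr.reshape(100, 100), 0)
        assert seg.n_canopy == 3_000
        assert seg.n_total == 10_000
        assert seg.cc == pytest.approx(0.3)
        # oracle: single-pass comparison yields the identical mask
        assert (seg.mask == (gr.reshape(100, 100) > 0)).all()

    def test_cc_monotone_nonincreasing_in_threshold(self, rng):
        gr = rng.integers(-255, 256, size=(60, 80)).astype(np.int16)
        ccs = [segment_canopy(gr, t).cc for t in range(-255, 256, 15)]
        assert all(a >= b for a, b in zip(ccs, ccs[1:]))

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            segment_canopy(np.zeros((2, 2), np.int16), 300)


def _between_class_variance(values, t):
    lo, hi = values[values <= t], values[values > t]
    if lo.size == 0 or hi.size == 0:
        return -np.inf
    n = values.size
    return (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2


class TestAutoThreshold:
    def test_bimodal_map_split_exactly(self):
        gr = np.array([-80] * 500 + [120] * 500, dtype=np.int16)
        t = auto_threshold(gr.reshape(20, 50))
        assert -80 <= t <= 119
        assert segment_canopy(gr.reshape(20, 50), t).cc == 0.5

    def test_matches_exhaustive_scan(self, rng):
        # oracle: scan all 511 candidate thresholds directly
        gr = np.concatenate([
            rng.normal(-60, 12, 900), rng.normal(90, 20, 1100)
        ]).round().clip(-255, 255).astype(np.int16)
        t = auto_threshold(gr.reshape(40, 50))
        scores = np.array([
            _between_class_variance(gr.astype(float), c)
            for c in range(-255, 256)
        ])
        best = int(np.flatnonzero(scores == scores.max())[0]) - 255
        assert t == best

    def test_alternating_map(self):
        gr = np.tile([-1, 1], 50).astype(np.int16).reshape(10, 10)
        t = auto_threshold(gr)
        assert -1 <= t <= 0
        assert segment_canopy(gr, t).cc == 0.5

    def test_constant_map_raises(self):
        with pytest.raises(ValueError, match="constant"):
            auto_threshold(np.full((5, 5), 7, dtype=np.int16))

    def test_agrees_with_skimage_on_shifted_data(self, rng):
        # independent implementation check: Otsu on a nonnegative copy
        skimage_filters = pytest.importorskip("skimage.filters")
        gr = np.concatenate([
            rng.normal(-40, 8, 1000), rng.normal(70, 10, 1000)
        ]).round().clip(-255, 255).astype(np.int16)
        t = auto_threshold(gr.reshape(40, 50))
        ref = skimage_filters.threshold_otsu(
            (gr + 255).astype(np.uint16), nbins=511)
        # skimage returns a bin value with canopy = values >= t convention
        assert abs((ref - 255) - t) <= 1


class TestFromFile:
    def test_full_green_canopy(self, tmp_path):
        path = tmp_path / "green.png"
        Image.fromarray(_uniform(30, 180, 40, (20, 20))).save(path)
        seg = cc_from_image_file(path)
        assert seg.cc == 1.0
        assert seg.image_path == str(path)

    def test_ground_truth_recovery(self, tmp_path, scene_042):
        cfg, img, mask = scene_042
        path = tmp_path / "scene.png"
        Image.fromarray(img).save(path)
        seg = cc_from_image_file(path, threshold=0)
        assert seg.cc == pytest.approx(mask.mean(), abs=0.01)

    def test_noiseless_scene_exact(self, tmp_path):
        cfg = ImageSceneConfig(target_cover=0.37, color_noise_sd=0.0,
                               seed=2)
        img, mask = generate_canopy_image(cfg)
        path = tmp_path / "clean.png"
        Image.fromarray(img).save(path)
        assert cc_from_image_file(path, 0).cc == mask.mean()

    def test_unreadable_file(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(OSError, match="broken.png"):
            cc_from_image_file(bad)

    def test_downsampling_robustness(self, tmp_path, scene_042):
        # block-averaging by 2 and 4 shifts CC by < 0.02
        _, img, mask = scene_042
        base = segment_canopy(compute_gr_index(img), 0).cc
        for k in (2, 4):
            h, w = (img.shape[0] // k) * k, (img.shape[1] // k) * k
            small = img[:h, :w].reshape(h // k, k, w // k, k, 3)
            small = small.mean(axis=(1, 3)).round().astype(np.uint8)
            cc = segment_canopy(compute_gr_index(small), 0).cc
            assert abs(cc - base) < 0.02


class TestBatch:
    def test_directory_batch_with_metadata(self, tmp_path):
        import pandas as pd

        truths = []
        for i, cover in enumerate([0.2, 0.5, 0.8]):
            cfg = ImageSceneConfig(width=160, height=120,
                                   target_cover=cover, seed=20 + i)
            img, mask = generate_canopy_image(cfg)
            Image.fromarray(img).save(tmp_path / f"img_{i}.png")
            truths.append(mask.mean())
        meta = pd.DataFrame({
            "image_path": [f"img_{i}.png" for i in range(3)],
            "site": "Xinxiang", "season": "2016-2017",
            "cultivar": "AK58", "n_rate_kg_ha": 150,
            "replicate": [1, 2, 3], "stage": "Feekes 5",
        })
        table = cc_table(tmp_path, meta, threshold=0)
        assert len(table) == 3
        assert list(table["replicate"]) == [1, 2, 3]
        assert np.allclose(table["cc"], truths, atol=0.01)
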