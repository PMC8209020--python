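"""Adaptive local-mean thresholding and artifact/hole cleanup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibrometry as fm
from fibrometry.errors import ValidationError
from fibrometry.segmentation import (
    adaptive_threshold,
    fill_small_holes,
    remove_artifacts,
)


def as_image(pixels, um_per_px=1.0):
    return fm.CalibratedImage(np.asarray(pixels, float), um_per_px=um_per_px)


def brute_force_threshold(pixels, window, offset):
    """Reference: explicit local mean with reflect padding, strict >."""
    h = window // 2
    # scipy's "reflect" boundary duplicates the edge sample (numpy "symmetric")
    padded = np.pad(pixels, h, mode="symmetric")
    out = np.zeros_like(pixels, dtype=bool)
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            local = padded[r : r + window, c : c + window].mean()
            out[r, c] = pixels[r, c] > local + offset
    return out


class TestAdaptiveThreshold:
    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pixels = rng.random((21, 17))
            mask = adaptive_threshold(as_image(pixels), window_px=5, offset=0.03)
            assert np.array_equal(mask.mask, brute_force_threshold(pixels, 5, 0.03))

    def test_single_hot_center_pixel_detected_alone(self):
        pixels = np.zeros((15, 15))
        pixels[7, 7] = 1.0
        mask = adaptive_threshold(as_image(pixels), window_px=15, offset=0.1)
        expected = np.zeros((15, 15), dtype=bool)
        expected[7, 7] = True
        assert np.array_equal(mask.mask, expected)

    def test_constant_image_gives_empty_mask(self):
        mask = adaptive_threshold(as_image(np.full((32, 32), 0.5)), offset=0.01)
        assert mask.n_foreground_px == 0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_larger_offset_shrinks_mask(self, seed):
        rng = np.random.default_rng(seed)
        img = as_image(rng.random((24, 24)))
        small = adaptive_threshold(img, offset=0.02).mask
        large = adaptive_threshold(img, offset=0.08).mask
        assert np.all(large <= small)

    def test_invariant_to_constant_intensity_shift(self):
        rng = np.random.default_rng(4)
        pixels = rng.random((32, 32)) * 0.5
        m1 = adaptive_threshold(as_image(pixels), offset=0.05).mask
        m2 = adaptive_threshold(as_image(pixels + 0.3), offset=0.05).mask
        assert np.array_equal(m1, m2)

    @pytest.mark.parametrize("window", [2, 0, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValidationError, match="window_px"):
            adaptive_threshold(as_image(np.zeros((16, 16))), window_px=window)


class TestRemoveArtifacts:
    def test_small_component_removed(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5:7, 5:10] = True  # 10 px
        out = remove_artifacts(
            fm.BinaryMask(mask, 1.0), min_object_px=50, circularity_cutoff=None
        )
        assert out.n_foreground_px == 0

    def test_line_kept_disk_removed_by_circularity(self):
        mask = np.zeros((80, 220), dtype=bool)
        mask[10, 5:205] = True  # 200 px line
        rr, cc = np.ogrid[:80, :220]
        disk = (rr - 50) ** 2 + (cc - 100) ** 2 <= 8**2  # ~200 px disk
        mask[disk] = True
        bm = fm.BinaryMask(mask, 1.0)
        out = remove_artifacts(bm, min_object_px=50, circularity_cutoff=0.6)
        assert out.mask[10, 100]
        assert not out.mask[50, 100]
        # independent sanity check of the discrimination: boundary-edge
        # perimeter puts the line's circularity far below the disk's
        def edge_perimeter(m):
            return (
                np.count_nonzero(m[:, :-1] != m[:, 1:])
                + np.count_nonzero(m[:-1, :] != m[1:, :])
            )

        line_only = np.zeros_like(mask)
        line_only[10, 5:205] = True
        disk_only = np.zeros_like(mask)
        disk_only[disk] = True
        # the edge-count perimeter overestimates smooth boundaries, so the
        # disk's circularity lands near 0.5 on this scale; the separation
        # between filament and blob remains an order of magnitude
        circ = lambda m: 4 * np.pi * m.sum() / edge_perimeter(m) ** 2
        assert circ(line_only) < 0.1 < 0.4 < circ(disk_only)

    def test_noop_configuration_is_identity(self):
        rng = np.random.default_rng(1)
        mask = rng.random((40, 40)) < 0.3
        bm = fm.BinaryMask(mask, 1.0)
        out = remove_artifacts(bm, min_object_px=0, circularity_cutoff=None)
        assert np.array_equal(out.mask, mask)

    def test_exclusion_mask_and_subset_property(self):
        rng = np.random.default_rng(2)
        mask = rng.random((40, 40)) < 0.4
        excl = np.zeros((40, 40), dtype=bool)
        excl[:20] = True
        out = remove_artifacts(
            fm.BinaryMask(mask, 1.0), min_object_px=5, exclusion_mask=excl
        )
        assert not out.mask[:20].any()
        assert np.all(out.mask <= mask)

    def test_exclusion_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="exclusion_mask"):
            remove_artifacts(
                fm.BinaryMask(np.zeros((8, 8), bool), 1.0),
                exclusion_mask=np.zeros((4, 4), bool),
            )


class TestFillSmallHoles:
    def test_pinhole_filled_mesh_hole_kept(self):
        mask = np.ones((60, 60), dtype=bool)
        mask[10, 10] = False  # 1 px pinhole
        mask[30:45, 30:45] = False  # 225 px real opening
        out = fill_small_holes(fm.BinaryMask(mask, 1.0), max_hole_px=40)
        assert out.mask[10, 10]
        assert not out.mask[35, 35]

    def test_border_background_never_filled(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:20, 10:20] = True
        out = fill_small_holes(fm.BinaryMask(mask, 1.0), max_hole_px=10**6)
        assert np.array_equal(out.mask, mask)


def test_final_mask_f1_above_0p8_on_presets(default_config):
    """Pixelwise F1 of the cleaned mask against ground truth on the two
    tissue presets (noise 0.05, shading 0.2)."""
    from fibrometry.preprocessing import (
        flatten_illumination,
        normalize_and_orient,
        tophat_enhance,
    )

    cfg = default_config
    for preset in ("tlf", "gluteal"):
        spec = fm.preset_spec(preset, seed=1)
        image, truth = fm.generate_network(spec)
        img = normalize_and_orient(image)
        img = flatten_illumination(img, cfg.background_scale_px)
        img = tophat_enhance(img, cfg.tophat_radius_px)
        mask = adaptive_threshold(img, cfg.threshold_window_px, cfg.threshold_offset)
        mask = remove_artifacts(
            mask, cfg.min_object_px, cfg.circularity_cutoff
        )
        mask = fill_small_holes(mask, cfg.fill_holes_px)
        gt = truth.foreground_mask
        tp = np.count_nonzero(mask.mask & gt)
        fp = np.count_nonzero(mask.mask & ~gt)
        fn = np.count_nonzero(~mask.mask & gt)
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.8, f"{preset}: F1={f1:.3f}"
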