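"""Skeletonization, branch points, length measurement, parameter summary."""


import numpy as np
import pytest

import fibrometry as fm
from fibrometry.errors import ValidationError
from fibrometry.morphometry import (
    find_branch_points,
    measure_length,
    skeletonize,
    summarize,
)

SQRT2 = np.sqrt(2.0)


def make_bar_mask(width_px=5, length_px=100, shape=(64, 120), um_per_px=1.0):
    mask = np.zeros(shape, dtype=bool)
    r0 = shape[0] // 2 - width_px // 2
    c0 = (shape[1] - length_px) // 2
    mask[r0 : r0 + width_px, c0 : c0 + length_px] = True
    return fm.BinaryMask(mask=mask, um_per_px=um_per_px)


def skeleton_of(mask_array, um_per_px=1.0):
    return fm.SkeletonImage(
        skeleton=np.asarray(mask_array, bool), branch_points=[], um_per_px=um_per_px
    )


def brute_force_length_um(skel, um_per_px):
    """O(n^2) enumeration of unique adjacent pixel pairs."""
    coords = np.argwhere(skel)
    total = 0.0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            dr = abs(coords[i][0] - coords[j][0])
            dc = abs(coords[i][1] - coords[j][1])
            if max(dr, dc) == 1:
                total += SQRT2 if dr + dc == 2 else 1.0
    return total * um_per_px


def brute_force_branch_points(skel):
    """Junction pixels by exhaustive neighbor count; 8-adjacent ones merged
    by union-find; returns the cluster count."""
    rows, cols = skel.shape
    junctions = []
    for r in range(rows):
        for c in range(cols):
            if not skel[r, c]:
                continue
            nbrs = sum(
                bool(skel[r + dr, c + dc])
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr or dc) and 0 <= r + dr < rows and 0 <= c + dc < cols
            )
            if nbrs >= 3:
                junctions.append((r, c))
    parent = {p: p for p in junctions}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, p in enumerate(junctions):
        for q in junctions[i + 1 :]:
            if max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1:
                rp, rq = find(p), find(q)
                if rp != rq:
                    parent[rq] = rp
    return len({find(p) for p in junctions})


class TestSkeletonize:
    def test_empty_mask_gives_empty_skeleton(self):
        out = skeletonize(fm.BinaryMask(np.zeros((32, 32), bool), 1.0))
        assert out.n_skeleton_px == 0
        assert out.branch_points == []

    def test_bar_thins_to_single_axis_path(self):
        mask = make_bar_mask(width_px=5, length_px=100)
        skel = skeletonize(mask)
        # one component, unit width, no junctions
        from scipy import ndimage as ndi

        _, n = ndi.label(skel.skeleton, structure=np.ones((3, 3), int))
        assert n == 1
        blocks = (
            skel.skeleton[:-1, :-1]
            & skel.skeleton[1:, :-1]
            & skel.skeleton[:-1, 1:]
            & skel.skeleton[1:, 1:]
        )
        assert not blocks.any()
        length_px = measure_length(skel) * 1000.0
        assert 96.0 <= length_px <= 100.0
        assert skel.branch_points == []

    def test_thin_diagonal_line_unchanged(self):
        mask = np.zeros((40, 40), dtype=bool)
        idx = np.arange(5, 35)
        mask[idx, idx] = True
        skel = skeletonize(fm.BinaryMask(mask, 1.0))
        assert np.array_equal(skel.skeleton, mask)

    def test_topology_preserved_component_count(self, tlf_image_truth):
        spec, _, truth = tlf_image_truth
        from scipy import ndimage as ndi

        mask = fm.BinaryMask(truth.foreground_mask, spec.um_per_px)
        skel = skeletonize(mask)
        s8 = np.ones((3, 3), int)
        _, n_mask = ndi.label(mask.mask, structure=s8)
        _, n_skel = ndi.label(skel.skeleton, structure=s8)
        assert n_mask == n_skel
        assert np.all(mask.mask[skel.skeleton])

    def test_spur_pruning_removes_short_junction_branches_only(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[15, 5:55] = True  # main path
        mask[12:15, 30] = True  # 3 px spur ending at a junction
        skel = skeletonize(fm.BinaryMask(mask, 1.0), prune_spurs_px=5)
        assert not skel.skeleton[12:15, 30].any()
        assert skel.skeleton[15, 5:55].all()
        # open tips of the main path are untouched
        assert skel.skeleton[15, 5] and skel.skeleton[15, 54]


class TestFindBranchPoints:
    def test_straight_line_has_none(self):
        line = np.zeros((20, 20), bool)
        line[10, 2:18] = True
        assert find_branch_points(skeleton_of(line)) == []

    def test_plus_sign_has_exactly_one(self):
        plus = np.zeros((21, 21), bool)
        plus[10, 2:19] = True
        plus[2:19, 10] = True
        points = find_branch_points(skeleton_of(plus))
        assert len(points) == 1
        assert points[0] == (10, 10)

    def test_y_junction_matches_exhaustive_enumeration(self):
        y = np.zeros((24, 24), bool)
        y[12:22, 11] = True
        for k in range(10):
            y[11 - k, 11 - k] = True
            y[11 - k, 11 + k] = True
        points = find_branch_points(skeleton_of(y))
        assert len(points) == brute_force_branch_points(y) == 1

    def test_nonthin_skeleton_warns(self):
        blob = np.ones((6, 6), bool)
        with pytest.warns(UserWarning, match="unit-width"):
            find_branch_points(skeleton_of(blob))

    def test_merge_radius_fuses_nearby_junctions(self):
        s = np.zeros((20, 40), bool)
        s[10, 2:38] = True
        s[7:10, 10] = True  # junction at (10,10)
        s[7:10, 14] = True  # junction at (10,14)
        skel = skeleton_of(s)
        assert len(find_branch_points(skel)) == 2
        assert len(find_branch_points(skel, merge_radius_px=5.0)) == 1


class TestMeasureLength:
    def test_horizontal_run_is_exact(self):
        s = np.zeros((5, 120), bool)
        s[2, 5:106] = True  # 101 pixels -> 100 orthogonal adjacencies
        assert measure_length(skeleton_of(s)) == pytest.approx(0.1)

    def test_diagonal_run_weighted_sqrt2(self):
        s = np.zeros((120, 120), bool)
        idx = np.arange(5, 106)
        s[idx, idx] = True
        expected_mm = 100 * SQRT2 / 1000.0
        assert measure_length(skeleton_of(s)) == pytest.approx(expected_mm)

    def test_matches_brute_force_on_random_sparse_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            s = rng.random((10, 10)) < 0.25
            got = measure_length(skeleton_of(s, um_per_px=2.0)) * 1000.0
            assert got == pytest.approx(brute_force_length_um(s, 2.0))

    def test_isolated_pixels_contribute_zero(self):
        s = np.zeros((10, 10), bool)
        s[1, 1] = s[5, 5] = s[8, 2] = True
        assert measure_length(skeleton_of(s)) == 0.0

    def test_pixel_count_estimator_and_bad_name(self):
        s = np.zeros((5, 10), bool)
        s[2, 1:9] = True
        assert measure_length(skeleton_of(s), estimator="pixel-count") == pytest.approx(
            8 / 1000.0
        )
        with pytest.raises(ValidationError, match="estimator"):
            measure_length(skeleton_of(s), estimator="geodesic")


class TestSummarize:
    def test_direct_area_fraction(self):
        mask = np.zeros((100, 100), bool)
        mask[:30, :30] = True  # 900 px
        bm = fm.BinaryMask(mask, 1.0)
        out = summarize(bm, skeletonize(bm))
        assert out.positive_area_pct == pytest.approx(9.0)

    def test_bar_thickness_near_true_width(self):
        mask = make_bar_mask(width_px=5, length_px=100, um_per_px=1.0)
        skel = skeletonize(mask)
        out = summarize(mask, skel)
        assert out.mean_thickness_um == pytest.approx(
            500.0 / (out.total_length_mm * 1000.0)
        )
        assert out.mean_thickness_um == pytest.approx(5.0, rel=0.15)

    def test_empty_mask_zeroes_and_undefined_thickness(self):
        bm = fm.BinaryMask(np.zeros((64, 64), bool), 1.0)
        out = summarize(bm, skeletonize(bm))
        assert out.positive_area_pct == 0.0
        assert out.bp_density_per_mm2 == 0.0
        assert out.total_length_mm == 0.0
        assert np.isnan(out.mean_thickness_um)
        assert not out.thickness_defined

    def test_thickness_length_area_identity_exact(self, tlf_image_truth, default_config):
        _, image, _ = tlf_image_truth
        out = fm.process_image(image, default_config)
        area_um2 = out.n_foreground_px * 1.0**2
        assert out.mean_thickness_um * out.total_length_mm * 1000.0 == pytest.approx(
            area_um2, rel=1e-12
        )
        assert out.bp_density_per_mm2 * out.image_area_mm2 == pytest.approx(
            out.n_branch_points, abs=1e-9
        )

    def test_calibration_equivariance(self):
        rng = np.random.default_rng(5)
        mask = rng.random((64, 64)) < 0.2
        out1 = summarize(
            fm.BinaryMask(mask, 1.0), skeletonize(fm.BinaryMask(mask, 1.0))
        )
        out2 = summarize(
            fm.BinaryMask(mask, 2.0), skeletonize(fm.BinaryMask(mask, 2.0))
        )
        assert out2.positive_area_pct == out1.positive_area_pct
        assert out2.total_length_mm == pytest.approx(2 * out1.total_length_mm)
        assert out2.image_area_mm2 == pytest.approx(4 * out1.image_area_mm2)
        if out1.n_branch_points:
            assert out2.bp_density_per_mm2 == pytest.approx(
                out1.bp_density_per_mm2 / 4
            )
        if out1.thickness_defined:
            assert out2.mean_thickness_um == pytest.approx(2 * out1.mean_thickness_um)

    def test_calibration_mismatch_rejected(self):
        bm = fm.BinaryMask(np.zeros((16, 16), bool), 1.0)
        sk = skeleton_of(np.zeros((16, 16), bool), um_per_px=2.0)
        with pytest.raises(ValidationError, match="calibration"):
            summarize(bm, sk)

    def test_shape_mismatch_rejected(self):
        bm = fm.BinaryMask(np.zeros((16, 16), bool), 1.0)
        sk = skeleton_of(np.zeros((16, 18), bool))
        with pytest.raises(ValidationError, match="shape"):
            summarize(bm, sk)


def test_branch_and_length_oracle_on_random_small_masks():
    """Spot version of the exhaustive oracle comparison (full run in the
    acceptance suite): counts and lengths agree exactly on random 8x8
    patterns with up to 12 foreground pixels."""
    rng = np.random.default_rng(2024)
    for _ in range(2000):
        n_fg = rng.integers(0, 13)
        s = np.zeros(64, dtype=bool)
        s[rng.choice(64, size=n_fg, replace=False)] = True
        s = s.reshape(8, 8)
        skel = skeleton_of(s)
        got_bp = len(find_branch_points(skel, warn_if_thick=False))
        assert got_bp == brute_force_branch_points(s)
        got_len = measure_length(skel) * 1000.0
        assert got_len == pytest.approx(brute_force_length_um(s, 1.0), abs=1e-9)
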