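import colorsys
import math

import numpy as np
import pytest

from pollenvision.cst_features import (
    CSTConfig,
    Contour,
    color_means,
    extract_contour,
    extract_cst,
    glcm,
    glcm_contrast_entropy,
    glcm_features,
    k_curvature_histogram,
    minimum_enclosing_circle,
    quantize_gray,
    shape_descriptors,
)
from pollenvision.dataset_io import SegmentedPollenImage, ValidationError

from conftest import disk_mask, ellipse_mask, noisy_image, square_mask


# ---------------------------------------------------------------------------
# Color

def _hsv_oracle(pixels, mask):
    """Per-pixel colorsys conversion-and-average reference."""
    h = s = v = r = 0.0
    n = 0
    for (row, col) in zip(*np.nonzero(mask)):
        rr, gg, bb = pixels[row, col] / 255.0
        hh, ss, vv = colorsys.rgb_to_hsv(rr, gg, bb)
        h, s, v, r = h + hh, s + ss, v + vv, r + rr
        n += 1
    return h / n, s / n, v / n, r / n


class TestColorMeans:
    def test_pure_red_foreground(self):
        px = np.zeros((8, 8, 3), np.uint8)
        px[..., 0] = 255
        img = SegmentedPollenImage(px, np.ones((8, 8), bool), "red")
        assert color_means(img) == (0.0, 1.0, 1.0, 1.0)

    def test_mid_gray_foreground(self):
        px = np.full((8, 8, 3), 128, np.uint8)
        img = SegmentedPollenImage(px, np.ones((8, 8), bool), "gray")
        h, s, v, r = color_means(img)
        assert h == 0.0 and s == 0.0
        assert v == pytest.approx(128 / 255)
        assert r == pytest.approx(128 / 255)

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        mask = rng.random((32, 32)) < 0.6
        mask[0, 0] = True
        img = SegmentedPollenImage(px, mask, "rand")
        got = color_means(img)
        want = _hsv_oracle(px.astype(float), mask)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_background_pixels_ignored(self):
        px = np.zeros((8, 8, 3), np.uint8)
        px[..., 0] = 255
        px[0, :] = 255  # white strip, excluded from mask
        mask = np.ones((8, 8), bool)
        mask[0, :] = False
        img = SegmentedPollenImage(px, mask, "red")
        assert color_means(img) == (0.0, 1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Contour

class TestExtractContour:
    def test_square_boundary_pixel_count(self):
        # brute force: boundary pixels of a filled 10x10 square = 36
        contour = extract_contour(square_mask(10))
        assert len(contour) == 36
        boundary = {tuple(p) for p in contour.points}
        truth = {
            (r, c)
            for r in range(10, 20) for c in range(10, 20)
            if r in (10, 19) or c in (10, 19)
        }
        assert boundary == truth

    def test_single_pixel_rejected(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        with pytest.raises(ValidationError, match="at least 4"):
            extract_contour(m)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            extract_contour(np.zeros((5, 5), bool))

    def test_disk_perimeter_near_circumference(self):
        contour = extract_contour(disk_mask(50))
        assert contour.perimeter() == pytest.approx(2 * math.pi * 50, rel=0.05)

    def test_starts_topmost_then_leftmost(self):
        contour = extract_contour(disk_mask(21))
        pts = contour.points
        top = pts[:, 0].min()
        leftmost_on_top = pts[pts[:, 0] == top][:, 1].min()
        assert tuple(pts[0]) == (top, leftmost_on_top)

    def test_counter_clockwise_orientation(self):
        pts = extract_contour(disk_mask(15)).points
        x, y = pts[:, 1].astype(float), -pts[:, 0].astype(float)
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed > 0


# ---------------------------------------------------------------------------
# Shape descriptors

class TestShapeDescriptors:
    def test_disk_scores_unity(self):
        sd = shape_descriptors(disk_mask(100))
        assert sd.shape_factor == pytest.approx(1.0, abs=0.02)
        assert sd.circularity == pytest.approx(1.0, abs=0.02)

    def test_square_closed_form(self):
        sd = shape_descriptors(square_mask(101))
        assert sd.shape_factor == pytest.approx(2 / math.pi, abs=0.02)
        assert sd.circularity == pytest.approx(2 / math.pi, abs=0.02)

    def test_ellipse_closed_form(self):
        sd = shape_descriptors(ellipse_mask(100, 50))
        assert sd.shape_factor == pytest.approx(0.5, abs=0.03)
        assert sd.circularity == pytest.approx(0.5, abs=0.03)

    def test_translation_and_rotation_invariance(self):
        m = ellipse_mask(40, 25, canvas=128)
        sd0 = shape_descriptors(m)
        sd_t = shape_descriptors(np.roll(m, (9, -13), axis=(0, 1)))
        sd_r = shape_descriptors(np.rot90(m))
        assert sd_t.shape_factor == pytest.approx(sd0.shape_factor, abs=1e-12)
        assert sd_t.circularity == pytest.approx(sd0.circularity, abs=1e-12)
        assert sd_r.shape_factor == pytest.approx(sd0.shape_factor, abs=1e-9)
        assert sd_r.circularity == pytest.approx(sd0.circularity, abs=1e-9)

    def test_disk_converges_to_continuous_limit(self):
        # errors shrink toward the continuous limit; at these radii they sit
        # at the 1e-4 rasterization-noise floor, so require a non-diverging
        # envelope rather than strict per-step monotonicity
        errs = []
        for r in (50, 100, 200):
            sd = shape_descriptors(disk_mask(r))
            errs.append(max(abs(sd.shape_factor - 1), abs(sd.circularity - 1)))
        assert max(errs) < 0.02
        assert errs[2] <= errs[0] + 5e-4

    def test_perimeter_mode_isoperimetric_quotient(self):
        sd = shape_descriptors(disk_mask(100), circularity_mode="perimeter")
        # digital perimeter overestimates; quotient stays below ~1
        assert 0.8 < sd.circularity <= 1.05


class TestMinimumEnclosingCircle:
    def test_exact_on_known_point_sets(self):
        pts = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 0.0], [10.0, 10.0]])
        center, radius = minimum_enclosing_circle(pts)
        np.testing.assert_allclose(center, [5.0, 5.0], atol=1e-9)
        assert radius == pytest.approx(math.hypot(5, 5), abs=1e-9)

    def test_covers_all_points_and_is_minimal(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(120, 2)) * [3.0, 9.0]
        center, radius = minimum_enclosing_circle(pts)
        d = np.linalg.norm(pts - center, axis=1)
        assert (d <= radius + 1e-9).all()
        # minimality: at least two points lie on the boundary
        assert (d >= radius - 1e-6).sum() >= 2


# ---------------------------------------------------------------------------
# k-curvature

def _curvature_oracle(points, k, edges):
    """Independent per-point angle loop."""
    n = len(points)
    angles = []
    for i in range(n):
        u = points[(i - k) % n] - points[i]
        v = points[(i + k) % n] - points[i]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            angles.append(0.0)
            continue
        c = np.clip(np.dot(u, v) / (nu * nv), -1, 1)
        angles.append(math.degrees(math.acos(c)))
    counts, _ = np.histogram(angles, bins=np.asarray(edges, dtype=float))
    return counts


class TestKCurvature:
    def test_counts_sum_to_contour_length(self):
        for mask in (disk_mask(30), ellipse_mask(50, 20), square_mask(25)):
            contour = extract_contour(mask)
            h = k_curvature_histogram(contour, CSTConfig(curvature_k=7))
            assert h.sum() == len(contour)

    def test_long_thin_rectangle_angle_structure(self):
        m = np.zeros((60, 240), bool)
        m[20:40, 20:220] = True  # 200 x 20 rectangle
        contour = extract_contour(m)
        config = CSTConfig()
        h = k_curvature_histogram(contour, config)
        edges = np.asarray(config.curvature_bin_edges)
        bin_180 = np.searchsorted(edges, 180.0, side="left") - 1
        bin_90 = np.searchsorted(edges, 90.0, side="right") - 1
        assert h[bin_180] > h.sum() / 2  # straight edges dominate
        assert h[bin_90] > 0  # four right-angle corners
        np.testing.assert_array_equal(
            h, _curvature_oracle(contour.points.astype(float), 15, edges)
        )

    def test_matches_per_point_oracle_on_random_blob(self, star_spec):
        from pollenvision.synthetic_data import generate_shape_mask
        mask = generate_shape_mask(star_spec, 256, 3)
        contour = extract_contour(mask)
        config = CSTConfig(curvature_k=9)
        got = k_curvature_histogram(contour, config)
        want = _curvature_oracle(
            contour.points.astype(float), 9, config.curvature_bin_edges
        )
        np.testing.assert_array_equal(got, want)

    def test_rotation_changes_bins_only_marginally(self):
        m = ellipse_mask(45, 20, canvas=128)
        config = CSTConfig(curvature_k=11)
        h0 = k_curvature_histogram(extract_contour(m), config)
        h1 = k_curvature_histogram(extract_contour(np.rot90(m)), config)
        assert np.abs(h0 - h1).max() <= 2

    def test_short_contour_rejected(self):
        contour = extract_contour(square_mask(3))
        with pytest.raises(ValidationError, match="too short"):
            k_curvature_histogram(contour, CSTConfig(curvature_k=50))


# ---------------------------------------------------------------------------
# GLCM

def _glcm_oracle(q, mask, dr, dc, levels):
    """Brute-force double-loop pair enumeration."""
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
    counts = counts + counts.T
    return counts / counts.sum()


_OFFSETS = {0.0: (0, 1), 45.0: (-1, 1), 90.0: (-1, 0), 135.0: (-1, -1)}


class TestGLCM:
    def test_hand_worked_two_by_two(self):
        q = np.array([[0, 255], [0, 255]])
        p = glcm(q, np.ones((2, 2), bool), 1, 0.0, 256)
        assert p[0, 255] == pytest.approx(0.5)
        assert p[255, 0] == pytest.approx(0.5)
        contrast, entropy = glcm_contrast_entropy(p)
        assert contrast == pytest.approx(65025.0)
        assert entropy == pytest.approx(math.log(2))

    def test_constant_image_zero_contrast_and_entropy(self):
        q = np.full((10, 10), 3)
        config = CSTConfig(gray_levels=8)
        for _, _, contrast, entropy in glcm_features(q, np.ones((10, 10), bool), config):
            assert contrast == 0.0
            assert entropy == 0.0

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        config = CSTConfig(gray_levels=8)
        for trial in range(5):
            q = rng.integers(0, 8, (16, 16))
            mask = rng.random((16, 16)) < 0.8
            mask[0, 0] = mask[1, 1] = True
            for d in config.glcm_distances:
                for a in config.glcm_angles:
                    dr, dc = _OFFSETS[a]
                    want = _glcm_oracle(q, mask, dr * d, dc * d, 8)
                    got = glcm(q, mask, d, a, 8)
                    np.testing.assert_allclose(got, want, atol=1e-12)

    def test_normalized_symmetric_invariants(self):
        rng = np.random.default_rng(1)
        q = rng.integers(0, 16, (24, 24))
        p = glcm(q, np.ones((24, 24), bool), 2, 45.0, 16)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(p, p.T)
        contrast, entropy = glcm_contrast_entropy(p)
        assert contrast >= 0
        assert 0 <= entropy <= math.log(16**2)

    def test_offset_without_valid_pairs_raises(self):
        q = np.zeros((3, 3), dtype=int)
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        with pytest.raises(ValidationError, match="distance=1"):
            glcm(q, mask, 1, 0.0, 4)

    def test_base2_entropy_option(self):
        q = np.array([[0, 255], [0, 255]])
        p = glcm(q, np.ones((2, 2), bool), 1, 0.0, 256)
        _, entropy = glcm_contrast_entropy(p, log_base="base-2")
        assert entropy == pytest.approx(1.0)


class TestQuantize:
    def test_range_and_levels(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        q = quantize_gray(px, 8)
        assert q.min() >= 0 and q.max() <= 7
        assert quantize_gray(np.full((4, 4), 255, np.uint8), 256).max() == 255


# ---------------------------------------------------------------------------
# Full vector

class TestExtractCST:
    def test_vector_length_with_defaults(self):
        img = noisy_image(disk_mask(40), seed=1)
        vec = extract_cst(img).to_array()
        assert len(vec) == 31  # 4 color + 2 shape + 9 bins + 2*(2*4) texture
        assert np.isfinite(vec).all()

    def test_deterministic(self):
        img = noisy_image(disk_mask(40), seed=2)
        v1 = extract_cst(img).to_array()
        v2 = extract_cst(img).to_array()
        np.testing.assert_array_equal(v1, v2)

    def test_slices_match_standalone_operations(self):
        config = CSTConfig()
        img = noisy_image(ellipse_mask(50, 30), seed=3)
        vec = extract_cst(img, config).to_array()
        np.testing.assert_allclose(vec[:4], color_means(img))
        sd = shape_descriptors(img.mask)
        np.testing.assert_allclose(vec[4:6], [sd.shape_factor, sd.circularity])
        curv = k_curvature_histogram(extract_contour(img.mask), config)
        np.testing.assert_allclose(vec[6:15], curv)
        q = quantize_gray(img.pixels, config.gray_levels)
        tex = [x for row in glcm_features(q, img.mask, config) for x in row[2:]]
        np.testing.assert_allclose(vec[15:], tex)

    def test_feature_names_align_with_length(self):
        config = CSTConfig(glcm_distances=(1,), glcm_angles=(0.0, 90.0))
        assert len(config.feature_names()) == config.n_features == 19


class TestCSTConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"curvature_k": 0},
        {"curvature_bin_edges": (0, 90)},  # does not reach 180
        {"curvature_bin_edges": (0, 90, 60, 180)},  # not increasing
        {"gray_levels": 1},
        {"glcm_distances": (0,)},
        {"entropy_log_base": "decimal"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CSTConfig(**kwargs)
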