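import math

import numpy as np
import pytest

from seedscan.morphometry import (
    feret_diameters,
    fit_ellipse,
    intensity_stats,
    measure_particle,
    shape_ratios,
)
from seedscan.scanio import ScanImage
from seedscan.segmentation import trace_boundary

from .conftest import mask_to_image, single_particle
from .oracles import (
    boundary_edge_count,
    brute_force_feret,
    brute_force_min_width,
    central_moments,
    random_blob,
    shoelace,
)

CAL600 = 25.4 / 600


def square_mask(side, pad=2):
    m = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def disk_mask(radius, pad=5):
    n = radius + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (xx * xx + yy * yy) <= radius * radius


class TestMeasureParticle:
    def test_10x10_square_calibration(self):
        img = mask_to_image(square_mask(10), dpi=600)
        rec = measure_particle(single_particle(square_mask(10)), img)
        assert rec.Area == pytest.approx(100 * CAL600 ** 2)
        assert rec.Width == pytest.approx(10 * CAL600)
        assert rec.Height == pytest.approx(10 * CAL600)
        assert rec.Feret == pytest.approx(math.sqrt(200) * CAL600)
        assert rec.MinFeret == pytest.approx(10 * CAL600)

    def test_single_pixel(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        img = mask_to_image(m, dpi=600)
        rec = measure_particle(single_particle(m), img)
        assert rec.Area == pytest.approx(CAL600 ** 2)
        assert rec.Perim == pytest.approx(4 * CAL600)
        assert rec.Solidity == 1.0
        assert rec.Feret == pytest.approx(math.sqrt(2) * CAL600)
        assert rec.MinFeret == pytest.approx(CAL600)

    def test_digital_disk_area_and_circ(self):
        radius = 20
        m = disk_mask(radius)
        # rasterization oracle: pixels whose centers lie inside the circle
        yy, xx = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
        p = single_particle(m)
        n_oracle = int(m.sum())
        assert p.pixel_count == n_oracle
        assert abs(n_oracle - math.pi * radius ** 2) / (math.pi * radius ** 2) < 0.015
        img = mask_to_image(m, dpi=25.4)
        rec = measure_particle(p, img)
        assert rec.Area == pytest.approx(n_oracle)
        # Circ under the crack-boundary perimeter (deliberate divergence
        # from smooth estimators): oracle = clamp(4*pi*A/P^2) with P from
        # independent edge enumeration
        P = boundary_edge_count(m)
        assert rec.Circ == pytest.approx(min(1.0, 4 * math.pi * n_oracle / P ** 2))

    def test_centroid_position(self):
        m = np.zeros((6, 8), bool)
        m[2:4, 3:5] = True  # 2x2 block, centre at (4.0, 3.0) in px
        img = mask_to_image(m, dpi=25.4)
        rec = measure_particle(single_particle(m), img)
        assert rec.X == pytest.approx(4.0)
        assert rec.Y == pytest.approx(3.0)
        assert rec.BX == pytest.approx(3.0)
        assert rec.BY == pytest.approx(2.0)

    def test_width_height_bound_area(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            m = random_blob(rng, size=12)
            img = mask_to_image(m, dpi=600)
            rec = measure_particle(single_particle(m), img)
            assert rec.Width * rec.Height >= rec.Area - 1e-12
            assert rec.MinFeret <= rec.Feret + 1e-12
            assert 0 < rec.Circ <= 1
            assert 0 < rec.Solidity <= 1
            assert rec.Major >= rec.Minor > 0


class TestFitEllipse:
    def test_disk_degenerate_angle(self):
        p = single_particle(disk_mask(15))
        major, minor, angle = fit_ellipse(p)
        assert major == pytest.approx(minor, rel=1e-3)
        assert angle == 0.0

    def test_rectangle_axis_ratio_vs_moment_oracle(self):
        m = np.zeros((14, 44), bool)
        m[2:12, 2:42] = True  # 40 x 10
        p = single_particle(m)
        major, minor, angle = fit_ellipse(p)
        assert angle == pytest.approx(0.0)
        assert major / minor == pytest.approx(4.0, rel=0.02)
        mu20, mu02, mu11 = central_moments(p.rows, p.cols)
        assert major / minor == pytest.approx(math.sqrt(mu20 / mu02), rel=1e-9)

    def test_rectangle_rotated_90(self):
        m = np.zeros((44, 14), bool)
        m[2:42, 2:12] = True
        _, _, angle = fit_ellipse(single_particle(m))
        assert angle == pytest.approx(90.0)

    def test_area_matched(self):
        rng = np.random.default_rng(3)
        m = random_blob(rng, size=12)
        p = single_particle(m)
        major, minor, _ = fit_ellipse(p)
        assert math.pi * (major / 2) * (minor / 2) == pytest.approx(p.pixel_count)


class TestFeret:
    def test_square_diagonal(self):
        poly = trace_boundary(single_particle(square_mask(10)))
        feret, angle, fx, fy, minferet = feret_diameters(poly)
        assert feret == pytest.approx(math.sqrt(200))
        assert minferet == pytest.approx(10.0)
        assert 0 <= angle < 180

    def test_single_pixel_unit_square(self):
        m = np.zeros((2, 2), bool)
        m[0, 0] = True
        poly = trace_boundary(single_particle(m))
        feret, _, fx, fy, minferet = feret_diameters(poly)
        assert feret == pytest.approx(math.sqrt(2))
        assert minferet == pytest.approx(1.0)
        # start endpoint: smaller y, then smaller x
        assert (fx, fy) in {(0.0, 0.0), (1.0, 0.0)}

    @pytest.mark.parametrize("seed", range(20))
    def test_random_polygons_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        m = random_blob(rng, size=8)
        poly = trace_boundary(single_particle(m))
        feret, angle, fx, fy, minferet = feret_diameters(poly)
        assert feret == pytest.approx(brute_force_feret(poly), abs=1e-9)
        assert minferet == pytest.approx(brute_force_min_width(poly), abs=1e-9)
        assert 0 <= angle < 180

    def test_feret_start_tiebreak(self):
        m = square_mask(4)
        poly = trace_boundary(single_particle(m))
        _, _, fx, fy, _ = feret_diameters(poly)
        # both diagonals tie; canonical pair then smaller-y endpoint
        assert fy == min(poly[:, 1])


class TestShapeRatios:
    def test_analytic_circle_is_one(self):
        r = 3.7
        circ, *_ = shape_ratios(math.pi * r * r, 2 * math.pi * r, 2 * r, 2 * r, math.pi * r * r)
        assert circ == 1.0

    def test_square_formula(self):
        s = 5.0
        circ, *_ = shape_ratios(s * s, 4 * s, s, s, s * s)
        assert circ == pytest.approx(math.pi / 4)

    def test_ar_round_identity(self):
        _, ar, rnd, _ = shape_ratios(math.pi * 2.0, 10.0, 4.0, 2.0, 7.0)
        assert ar == 2.0
        assert rnd == 0.5
        assert rnd * ar == 1.0

    @pytest.mark.parametrize("bad", [(-1, 1, 1, 1, 1), (1, 0, 1, 1, 1), (1, 1, 1, 1, -2)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            shape_ratios(*bad)


class TestIntensityStats:
    def make_img(self, mask, values):
        px = np.zeros(mask.shape, dtype=np.int64)
        px[mask] = values
        return ScanImage(pixels=px.astype(np.uint8), dpi=25.4)

    def test_binary_particle_skew_kurt_missing(self):
        m = square_mask(10)
        p = single_particle(m)
        img = self.make_img(m, 1)
        intden, raw, median, skew, kurt, xm, ym = intensity_stats(p, img)
        assert raw == 100.0
        assert skew is None and kurt is None

    def test_constant_255_weighted_centroid(self):
        m = square_mask(6)
        p = single_particle(m)
        img = self.make_img(m, 255)
        rec = measure_particle(p, img)
        assert rec.XM == pytest.approx(rec.X)
        assert rec.YM == pytest.approx(rec.Y)

    def test_three_pixel_median_and_sum(self):
        m = np.zeros((1, 3), bool)
        m[0, :] = True
        p = single_particle(m)
        img = self.make_img(m, np.array([10, 20, 40]))
        intden, raw, median, skew, kurt, _, _ = intensity_stats(p, img)
        assert median == 20.0
        assert raw == 70.0  # direct summation oracle
        assert skew is not None and kurt is not None


class TestInvariantProperties:
    def test_scale_equivariance(self):
        m = random_blob(np.random.default_rng(11), size=14)
        p = single_particle(m)
        r1 = measure_particle(p, mask_to_image(m, dpi=600))
        r2 = measure_particle(p, mask_to_image(m, dpi=1200))
        for name in ("Feret", "MinFeret", "Perim", "Major", "Minor", "Width"):
            assert getattr(r2, name) == pytest.approx(getattr(r1, name) / 2)
        assert r2.Area == pytest.approx(r1.Area / 4)
        for name in ("Circ", "AR", "Round", "Solidity"):
            assert getattr(r2, name) == pytest.approx(getattr(r1, name))

    @pytest.mark.parametrize("angle", [0.0, 37.0, 90.0])
    def test_rotation_robustness(self, angle):
        # smooth ellipse silhouette rasterized at several orientations
        a, b = 40.0, 16.0
        th = math.radians(angle)
        n = 60
        yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
        u = math.cos(th) * xx + math.sin(th) * yy
        v = -math.sin(th) * xx + math.cos(th) * yy
        m = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        rec = measure_particle(single_particle(m), mask_to_image(m, dpi=25.4))
        assert rec.Area == pytest.approx(math.pi * a * b, rel=0.03)
        assert rec.Feret == pytest.approx(2 * a, rel=0.03)
        assert rec.AR == pytest.approx(a / b, rel=0.03)

    def test_round_ar_product_exact(self):
        m = np.zeros((14, 44), bool)
        m[2:12, 2:42] = True
        rec = measure_particle(single_particle(m), mask_to_image(m, dpi=600))
        assert rec.Round * rec.AR == 1.0

    def test_rectangle_solidity_exact(self):
        rec = measure_particle(
            single_particle(square_mask(9)), mask_to_image(square_mask(9), dpi=600)
        )
        assert rec.Solidity == 1.0
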