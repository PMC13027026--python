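import numpy as np
import pytest
from skimage.morphology import erosion as skimage_erosion

from semmorph import (
    MicrographPair,
    SceneParams,
    erode_mask,
    fit_poly_surface,
    generate_scene,
    labels_to_regions,
    measure_pair,
    texture_value,
)

from conftest import ellipse_mask, scene_pair


def square(side, canvas=40):
    m = np.zeros((canvas, canvas), bool)
    off = (canvas - side) // 2
    m[off : off + side, off : off + side] = True
    return m


def disc(radius, canvas=80):
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    c = canvas // 2
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def region_with_image(mask, image01):
    """A single-label region plus a float image already on the 0-255 scale."""
    pair = MicrographPair(image=np.zeros(mask.shape), label_mask=mask.astype(np.int64))
    (reg,) = labels_to_regions(pair)
    return reg, np.asarray(image01) * 255.0


def coords_grid(mask):
    rows, cols = np.nonzero(mask)
    return np.column_stack([cols, rows]).astype(float)


class TestErodeMask:
    def test_square_shrinks_six_pixels_per_side_per_iteration(self):
        assert erode_mask(square(20)).sum() == 64  # 8 x 8

    def test_small_square_vanishes(self):
        assert erode_mask(square(12)).sum() == 0

    def test_disc_matches_reference_implementation(self):
        d = disc(30)
        ours = erode_mask(d)
        ref = skimage_erosion(skimage_erosion(d, np.ones((7, 7))), np.ones((7, 7)))
        assert np.array_equal(ours, ref.astype(bool))
        # geometric envelope: between the inscribed diagonal radius and the
        # axis-aligned radius of the doubly-eroded disc
        inner, outer = disc(30 - 6 * np.sqrt(2) - 0.5), disc(24)
        assert np.all(ours[inner])      # contains the safe inner disc
        assert not np.any(ours & ~outer)  # never exceeds the axis radius


class TestFitPolySurface:
    def test_constant_field_recovered_exactly(self):
        mask = square(20)
        fit = fit_poly_surface(coords_grid(mask), np.full(int(mask.sum()), 0.37))
        assert fit.valid
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
        assert fit.coefficients[0] == pytest.approx(0.37)
        assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-9)

    def test_field_in_model_span_has_zero_residual(self):
        mask = disc(15, canvas=40)
        coords = coords_grid(mask)
        x, y = coords[:, 0], coords[:, 1]
        z = 0.2 + 0.01 * x - 0.02 * y + 0.003 * x * y
        fit = fit_poly_surface(coords, z)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(5)
        mask = disc(20, canvas=50)
        coords = coords_grid(mask)
        z = rng.uniform(0, 1, len(coords))
        fit = fit_poly_surface(coords, z)
        x, y = coords[:, 0] - coords[:, 0].mean(), coords[:, 1] - coords[:, 1].mean()
        scale = max(np.abs(x).max(), np.abs(y).max())
        x, y = x / scale, y / scale
        design = np.column_stack([np.ones_like(x), x, y, x * x, y * y, x * y])
        resid = z - design @ np.linalg.lstsq(design, z, rcond=None)[0]
        assert np.all(np.abs(design.T @ resid) < 1e-8 * len(z))

    def test_uniform_noise_rms_analytic(self):
        # uniform noise on [-eps, eps] has rms eps/sqrt(3)
        rng = np.random.default_rng(6)
        eps = 0.05
        side = 100  # 10^4 pixels
        coords = coords_grid(np.ones((side, side), bool))
        z = 0.5 + rng.uniform(-eps, eps, side * side)
        fit = fit_poly_surface(coords, z)
        assert fit.rms_residual == pytest.approx(eps / np.sqrt(3), rel=0.05)

    def test_collinear_pixels_rank_deficient(self):
        coords = np.column_stack([np.arange(10.0), np.zeros(10)])
        fit = fit_poly_surface(coords, np.linspace(0, 1, 10))
        assert not fit.valid

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            fit_poly_surface(np.zeros((5, 2)), np.zeros(5))


class TestTextureValue:
    def smooth_cell(self, gradient=(0.0, 0.0)):
        mask = ellipse_mask((120, 120), 60, 60, 35, 22, 25)
        yy, xx = np.mgrid[0:120, 0:120]
        phi = np.deg2rad(25)
        u = (xx - 60) * np.cos(phi) + (yy - 60) * np.sin(phi)
        v = -(xx - 60) * np.sin(phi) + (yy - 60) * np.cos(phi)
        dome = 0.68 - 0.26 * ((u / 35) ** 2 + (v / 22) ** 2)
        img = 0.22 + np.where(mask, dome - 0.22, 0.0)
        img = img + gradient[0] * xx + gradient[1] * yy
        return mask, img

    def test_smooth_dome_has_near_zero_texture(self):
        mask, img = self.smooth_cell(gradient=(4e-5, 6e-5))
        reg, image = region_with_image(mask, img)
        tex = texture_value(reg, image)
        assert tex.valid
        assert tex.texture_value < 0.002

    def test_invariant_to_planar_gradient(self):
        mask, img1 = self.smooth_cell(gradient=(4e-5, 6e-5))
        _, img2 = self.smooth_cell(gradient=(8e-5, 12e-5))
        reg, image1 = region_with_image(mask, img1)
        _, image2 = region_with_image(mask, img2)
        t1 = texture_value(reg, image1).texture_value
        t2 = texture_value(reg, image2).texture_value
        assert t1 == pytest.approx(t2, abs=1e-6)

    def test_invariant_to_any_surface_in_model_span(self):
        rng = np.random.default_rng(7)
        mask, img = self.smooth_cell()
        noise = np.where(mask, rng.normal(0, 0.02, mask.shape), 0.0)
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        span = 1e-4 * xx + 2e-4 * yy + 1e-6 * xx**2 - 2e-6 * yy**2 + 1e-6 * xx * yy
        reg, image = region_with_image(mask, img + noise)
        _, image_shifted = region_with_image(mask, img + noise + span)
        t1 = texture_value(reg, image).texture_value
        t2 = texture_value(reg, image_shifted).texture_value
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_scales_linearly_with_contrast(self):
        rng = np.random.default_rng(8)
        mask, img = self.smooth_cell()
        noisy = img + np.where(mask, rng.normal(0, 0.02, mask.shape), 0.0)
        reg, image = region_with_image(mask, noisy)
        t1 = texture_value(reg, image).texture_value
        t2 = texture_value(reg, image * 0.5).texture_value
        assert t2 == pytest.approx(0.5 * t1, rel=1e-9)

    def test_never_beats_planar_fit(self):
        rng = np.random.default_rng(9)
        mask, img = self.smooth_cell()
        noisy = img + np.where(mask, rng.normal(0, 0.03, mask.shape), 0.0)
        reg, image = region_with_image(mask, noisy)
        eroded = erode_mask(reg.mask)
        rows, cols = np.nonzero(eroded)
        r0, _, c0, _ = reg.bbox
        z = image[rows + r0, cols + c0] / 255.0
        x, y = (cols + c0).astype(float), (rows + r0).astype(float)
        planar = np.column_stack([np.ones_like(x), x, y])
        resid = z - planar @ np.linalg.lstsq(planar, z, rcond=None)[0]
        planar_rms = np.sqrt(np.mean(resid**2))
        assert texture_value(reg, image).texture_value <= planar_rms + 1e-12

    def test_small_eroded_region_flagged_invalid(self):
        reg, image = region_with_image(square(14, canvas=30), np.ones((30, 30)) * 0.5)
        tex = texture_value(reg, image)
        assert not tex.valid and tex.eroded_pixels < 50

    def test_generator_amplitude_recovered(self):
        values = []
        for seed in (21, 22):
            scene = generate_scene(
                SceneParams(n_cells=25, occluded_fraction=0.0,
                            chain_probability=0.0, roughness_amplitude=0.02,
                            seed=seed)
            )
            cells, _ = measure_pair(scene_pair(scene))
            values.extend(cells.loc[cells.texture_valid, "texture_value"])
        assert np.mean(values) == pytest.approx(0.02, rel=0.15)

    def test_plausible_range_on_study_like_scenes(self, default_measurement):
        cells, _ = default_measurement
        vals = cells.loc[cells.kept & cells.texture_valid, "texture_value"]
        # study-like roughness levels produce per-cell values of order 1e-2
        assert 0.005 < vals.mean() < 0.05
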