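import numpy as np
import pytest
from scipy.signal import find_peaks

from oracles import brute_disc_pixel_count
from synapsepol.errors import (
    DegenerateRoiError,
    EmptyCohortError,
    InterfaceOutOfStackError,
    NoInterfaceSignalError,
)
from synapsepol.interface_geometry import (
    InterfaceProjection,
    cohort_depletion,
    delimit_is_area,
    factin_low_area,
    intensity_profile,
    project_interface,
)
from synapsepol.scene import ImageScene
from synapsepol.segmentation import ConjugateGeometry, segment_conjugate


def ring_raster(shape=(128, 128), outer=30.0, inner=None, level=160.0):
    """Bright disc (inner=None) or annulus with dark interior of radius inner."""
    yy, xx = np.indices(shape)
    cy, cx = shape[0] / 2, shape[1] / 2
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    img = np.where(r <= outer, level, 0.0)
    if inner is not None:
        img[r < inner] = 0.0
    return img


def make_3d_geometry(vol_shape, is_centroid, is_axis, pixel_size=0.25, z_step=0.5):
    mask = np.ones(vol_shape, bool)
    return ConjugateGeometry(
        t_cell_mask=mask, apc_mask=np.zeros(vol_shape, bool),
        contact_segment=np.array([[0, 0, 0]]),
        cell_centroid=np.array(vol_shape, float) / 2,
        is_centroid=np.asarray(is_centroid, float),
        is_axis=np.asarray(is_axis, float),
        pixel_size=pixel_size, z_step=z_step,
    )


class TestProjectInterface:
    def test_axis_along_z_equals_substack_projection(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 100, size=(9, 16, 16))
        scene = ImageScene(
            data=vol[None, :, None], channel_roles={"actin": 0},
            pixel_size=0.25, z_step=0.5,
        )
        geom = make_3d_geometry((9, 16, 16), is_centroid=(4, 8, 8), is_axis=(1.0, 0, 0))
        faceon = project_interface(scene, geom, slab_depth_um=1.5)
        # 1.5 um slab at z_step 0.5 um = planes 4 +/- 1.5 -> 3..5
        np.testing.assert_array_equal(faceon, vol[3:6].max(axis=0))

    def test_faceon_matches_rendered_ring(self, zstack_scene, cytosol_seg_config):
        scene, truth = zstack_scene
        geom = segment_conjugate(scene, config=cytosol_seg_config, volumetric=True)
        faceon = project_interface(scene, geom)
        rf = truth.extras["facet_radius_px"]
        r_low = np.sqrt(truth.true_depletion_ratio) * rf
        yy, xx = np.indices(faceon.shape)
        r = np.sqrt((yy - faceon.shape[0] / 2) ** 2 + (xx - faceon.shape[1] / 2) ** 2)
        expected = np.where(r <= rf, 160.0, 0.0)
        expected[r < r_low] = 8.0
        from scipy import ndimage as ndi

        expected = ndi.gaussian_filter(expected, 1.0)  # mimic trilinear edge softening
        sel = r <= rf + 4
        corr = np.corrcoef(faceon[sel], expected[sel])[0, 1]
        assert corr >= 0.95

    def test_slab_deeper_than_stack_rejected(self, zstack_scene, cytosol_seg_config):
        scene, _ = zstack_scene
        geom = segment_conjugate(scene, config=cytosol_seg_config, volumetric=True)
        with pytest.raises(InterfaceOutOfStackError):
            project_interface(scene, geom, slab_depth_um=100.0)

    def test_2d_geometry_rejected(self, zstack_scene):
        scene, _ = zstack_scene
        geom_2d = ConjugateGeometry(
            t_cell_mask=np.ones((8, 8), bool), apc_mask=np.zeros((8, 8), bool),
            contact_segment=np.array([[0, 0]]), cell_centroid=np.array([4.0, 4.0]),
            is_centroid=np.array([4.0, 7.0]), is_axis=np.array([0.0, 1.0]),
            pixel_size=scene.pixel_size,
        )
        with pytest.raises(InterfaceOutOfStackError):
            project_interface(scene, geom_2d)


class TestDelimitIsArea:
    def test_full_disc_area(self):
        img = ring_raster(outer=30.0)
        region, area = delimit_is_area(img, pixel_size=1.0)
        expected = brute_disc_pixel_count((128, 128), (64.0, 64.0), 30.0)
        assert area == pytest.approx(expected, rel=0.05)

    def test_annulus_interior_filled(self):
        img = ring_raster(outer=30.0, inner=20.0)
        region, area = delimit_is_area(img, pixel_size=1.0)
        assert region[64, 64]  # hole filled
        expected = brute_disc_pixel_count((128, 128), (64.0, 64.0), 30.0)
        assert area == pytest.approx(expected, rel=0.05)

    def test_blank_raster_rejected(self):
        with pytest.raises(NoInterfaceSignalError):
            delimit_is_area(np.zeros((64, 64)), pixel_size=1.0)

    def test_area_in_physical_units(self):
        img = ring_raster(outer=30.0)
        _, area_1 = delimit_is_area(img, pixel_size=1.0)
        _, area_2 = delimit_is_area(img, pixel_size=0.5)
        assert area_2 == pytest.approx(area_1 * 0.25)


class TestFactinLowArea:
    def test_uniform_region_no_depletion(self):
        img = ring_raster(outer=30.0)
        region, _ = delimit_is_area(img, pixel_size=1.0)
        proj = factin_low_area(img, region, pixel_size=1.0)
        assert proj.area_ratio == 0.0
        assert not proj.depleted

    def test_half_radius_ring_quarter_ratio(self):
        img = ring_raster(outer=30.0, inner=15.0)
        region, _ = delimit_is_area(img, pixel_size=1.0)
        proj = factin_low_area(img, region, pixel_size=1.0)
        assert proj.area_ratio == pytest.approx(0.25, abs=0.02)
        assert proj.depleted

    def test_small_hole_below_cutoff_not_depleted(self):
        img = ring_raster(outer=30.0, inner=8.0)  # (8/30)^2 ~ 0.07 < 0.1
        region, _ = delimit_is_area(img, pixel_size=1.0)
        proj = factin_low_area(img, region, pixel_size=1.0, cutoff=0.1)
        assert proj.area_ratio < 0.1
        assert not proj.depleted

    def test_peripheral_gap_not_counted_as_central(self):
        img = ring_raster(outer=30.0)
        yy, xx = np.indices(img.shape)
        r = np.sqrt((yy - 64) ** 2 + (xx - 64 - 24) ** 2)
        img[r < 5] = 0.0  # dark notch near the rim, not central
        region, _ = delimit_is_area(img, pixel_size=1.0)
        proj = factin_low_area(img, region, pixel_size=1.0)
        assert proj.area_ratio < 0.05

    def test_intensity_scaling_invariance(self):
        img = ring_raster(outer=30.0, inner=15.0)
        region, _ = delimit_is_area(img, pixel_size=1.0)
        p1 = factin_low_area(img, region, pixel_size=1.0)
        p2 = factin_low_area(img * 11.0, region, pixel_size=1.0)
        assert p1.area_ratio == pytest.approx(p2.area_ratio)

    def test_ratio_bounds(self):
        img = ring_raster(outer=30.0, inner=29.0)
        region, _ = delimit_is_area(img, pixel_size=1.0)
        proj = factin_low_area(img, region, pixel_size=1.0)
        assert 0.0 <= proj.area_ratio <= 1.0
        assert proj.factin_low_area <= proj.is_area


class TestIntensityProfile:
    def test_constant_image_flat(self):
        img = np.full((64, 64), 42.0)
        pos, vals = intensity_profile(img, (32, 5), (32, 58))
        np.testing.assert_allclose(vals, 42.0)

    def test_ring_diameter_two_maxima(self):
        img = ring_raster(outer=30.0, inner=26.0)
        _, vals = intensity_profile(img, (64, 20), (64, 108), linewidth=3)
        peaks, _ = find_peaks(vals, height=100.0, plateau_size=1)
        assert len(peaks) == 2

    def test_zero_length_rejected(self):
        with pytest.raises(DegenerateRoiError):
            intensity_profile(np.zeros((32, 32)), (5, 5), (5, 5))

    def test_positions_in_um(self):
        img = np.full((64, 64), 1.0)
        pos, vals = intensity_profile(img, (32, 0), (32, 40), pixel_size=0.25)
        assert pos[1] - pos[0] == pytest.approx(0.25)


class TestCohortDepletion:
    @staticmethod
    def proj(ratio, cutoff=0.1):
        empty = np.zeros((1, 1), bool)
        return InterfaceProjection(
            faceon=np.zeros((1, 1)), is_region=empty, low_region=empty,
            is_area=1.0, factin_low_area=ratio, area_ratio=ratio,
            depleted=ratio > cutoff, cutoff_used=cutoff,
        )

    def test_direct_count(self):
        projs = [self.proj(r) for r in (0.3, 0.05, 0.2, 0.0)]
        assert cohort_depletion(projs) == pytest.approx(50.0)

    def test_all_depleted(self):
        assert cohort_depletion([self.proj(0.4), self.proj(0.2)]) == 100.0

    def test_empty(self):
        with pytest.raises(EmptyCohortError):
            cohort_depletion([])
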