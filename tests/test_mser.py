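import numpy as np
import pytest

from wormfreq.mser import (
    MserParams,
    MserRegion,
    detect_msers,
    min_circumscribed_ellipse,
    orientation_profile,
)

from .oracles import ellipse_area, mvee_multiplicative


def _disk(h, w, cy, cx, r, value):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2) * float(value)


class TestDetector:
    def test_single_disk_single_region(self):
        img = _disk(60, 60, 30, 30, 8, 200)
        regions = detect_msers(img, MserParams())
        assert len(regions) == 1
        true_area = int((img > 0).sum())
        assert abs(regions[0].area - true_area) <= 0.05 * true_area

    def test_nested_disks_two_regions(self):
        img = _disk(120, 120, 60, 60, 20, 100) + _disk(120, 120, 60, 60, 8, 100)
        regions = detect_msers(img, MserParams())
        assert len(regions) == 2
        a_small, a_large = regions[0].area, regions[1].area
        assert a_small < a_large  # sorted ascending
        assert abs(a_small - int((_disk(120, 120, 60, 60, 8, 1) > 0).sum())) <= 5
        assert abs(a_large - int((_disk(120, 120, 60, 60, 20, 1) > 0).sum())) <= 15
        # nesting: small region pixels inside the large one
        large_set = {tuple(p) for p in regions[1].pixels}
        assert all(tuple(p) in large_set for p in regions[0].pixels)

    def test_constant_frame_no_regions(self):
        assert detect_msers(np.zeros((30, 30)), MserParams()) == []
        assert detect_msers(np.full((30, 30), 5.0), MserParams(), scale=5.0) == []

    def test_min_area_respected(self):
        img = _disk(40, 40, 20, 20, 2, 200)  # ~13 px disk
        assert detect_msers(img, MserParams(min_area=30)) == []


class TestEllipse:
    def _region(self, pix):
        pix = np.asarray(pix)
        return MserRegion(pixels=pix, area=len(pix), level=0, stability=0.0)

    def test_axis_aligned_rectangle(self):
        pix = np.argwhere(np.ones((4, 20), bool))  # 4 rows x 20 cols
        e = min_circumscribed_ellipse(self._region(pix))
        assert e.orientation == pytest.approx(0.0, abs=1e-6)
        assert e.semi_major > e.semi_minor

    def test_rotated_rectangle_boundary_angle(self):
        pix = np.argwhere(np.ones((20, 4), bool))
        e = min_circumscribed_ellipse(self._region(pix))
        assert e.orientation == pytest.approx(np.pi / 2, abs=1e-6)

    def test_random_blob_against_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.integers(0, 30, size=(30, 2))
        e = min_circumscribed_ellipse(self._region(pts))
        area_impl = np.pi * e.semi_major * e.semi_minor
        c, a = mvee_multiplicative(pts[:, ::-1].astype(float))
        assert area_impl == pytest.approx(ellipse_area(a), rel=0.01)

    def test_contains_all_pixel_centers(self):
        rng = np.random.default_rng(6)
        pts = rng.integers(0, 25, size=(40, 2)).astype(float)
        e = min_circumscribed_ellipse(self._region(pts))
        # transform pixel centers into the ellipse frame and check radii
        cy, cx = e.center
        d = pts - [cy, cx]
        ang = e.orientation
        rot = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
        xy = d[:, ::-1] @ rot.T  # (x, y) in ellipse axes
        val = (xy[:, 0] / e.semi_major) ** 2 + (xy[:, 1] / e.semi_minor) ** 2
        assert val.max() <= 1.0 + 1e-6

    def test_collinear_degenerates_to_line(self):
        pix = np.array([[3, c] for c in range(10)])
        e = min_circumscribed_ellipse(self._region(pix), degenerate_eps=0.5)
        assert e.orientation == pytest.approx(0.0, abs=1e-9)
        assert e.semi_minor == pytest.approx(0.5)


class TestOrientationProfile:
    def test_linear_interpolation_example(self):
        prof = orientation_profile([100, 400], [0.2, 0.6], 4, 100, 400)
        np.testing.assert_allclose(prof.query_areas, [100, 200, 300, 400])
        np.testing.assert_allclose(prof.psi, [0.2, 1 / 3, 7 / 15, 0.6], atol=1e-9)

    def test_single_region_constant_profile_recenters_to_zero(self):
        prof = orientation_profile([150], [0.7], 5, 100, 400)
        np.testing.assert_allclose(prof.psi, 0.7)
        np.testing.assert_allclose(prof.recentered, np.zeros(5), atol=1e-12)

    def test_symmetric_angles_recentering(self):
        prof = orientation_profile([10, 20, 30], [0.1, 0.2, 0.3], 3, 10, 30)
        assert prof.circ_mean == pytest.approx(0.2, abs=1e-12)
        np.testing.assert_allclose(prof.recentered, [-0.1, 0.0, 0.1], atol=1e-12)

    def test_empty_regions_flagged(self):
        prof = orientation_profile([], [], 4, 10, 40)
        assert prof.empty
        np.testing.assert_array_equal(prof.recentered, np.zeros(4))

    def test_profile_length_always_n(self):
        rng = np.random.default_rng(7)
        for n_regions in (0, 1, 2, 5, 9):
            areas = np.sort(rng.uniform(10, 500, n_regions))
            psis = rng.uniform(-np.pi / 2, np.pi / 2, n_regions)
            prof = orientation_profile(areas, psis, 6, 20, 450)
            assert len(prof.recentered) == 6

    def test_recentered_circular_mean_is_zero(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = rng.integers(2, 8)
            areas = np.sort(rng.uniform(10, 500, n)) + np.arange(n)  # distinct
            psis = rng.uniform(-np.pi / 2, np.pi / 2, n)
            prof = orientation_profile(areas, psis, 5, 20, 450)
            resid = np.exp(2j * prof.recentered).sum()
            assert abs(np.angle(resid)) < 1e-9 or abs(resid) < 1e-9

    def test_rotation_shifts_raw_but_not_recentered(self):
        """Adding a constant rotation to every orientation (what a rigid
        rotation of the frame does, modulo pi) leaves the recentered profile
        unchanged -- the contract the recentering exists to provide."""
        rng = np.random.default_rng(9)
        areas = np.sort(rng.uniform(50, 400, 5))
        psis = rng.uniform(-0.4, 0.4, 5)
        base = orientation_profile(areas, psis, 4, 60, 380)
        for theta in (0.3, np.pi / 2, 1.2):
            shifted = np.mod(psis + theta + np.pi / 2, np.pi) - np.pi / 2
            prof = orientation_profile(areas, shifted, 4, 60, 380)
            np.testing.assert_allclose(prof.recentered, base.recentered, atol=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            orientation_profile([10], [0.1], 0, 1, 2)
        with pytest.raises(ValueError):
            orientation_profile([10], [0.1], 3, 5, 5)


def test_rotated_worm_frame_recentered_profile_invariant(worm_video):
    """90-degree grid rotation of a worm frame: raw orientations shift by
    pi/2 (mod pi), recentered profiles match."""
    from wormfreq.video import estimate_background, subtract_background

    stack, _ = worm_video
    frame = subtract_background(stack, estimate_background(stack)).frames[10]
    params = MserParams()

    def profile(f):
        regs = detect_msers(f, params)
        assert len(regs) >= 2, "worm frame should yield multiple stable regions"
        areas = [r.area for r in regs]
        psis = [min_circumscribed_ellipse(r).orientation for r in regs]
        return orientation_profile(areas, psis, 4, min(areas), max(areas))

    p0 = profile(frame)
    p90 = profile(np.ascontiguousarray(np.rot90(frame)))
    np.testing.assert_allclose(p90.recentered, p0.recentered, atol=5e-3)
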