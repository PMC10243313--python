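"""Film pipeline: OD arithmetic, calibration, fiducials, alignment."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from vaudit.dose_model import DoseGrid2D
from vaudit.errors import ArgumentError, CalibrationError, FiducialDetectionError, FormatError
from vaudit.film import (
    FiducialSet,
    FilmScan,
    Rect,
    ScanLayout,
    align_to_isocenter,
    apply_calibration,
    correct_nonuniformity,
    detect_fiducials,
    fit_calibration,
    mean_region_od,
    optical_density,
    read_scan,
    red_channel,
)


class TestReadScan:
    def _write(self, path, pixels, dpi=150):
        tifffile.imwrite(path, pixels, resolution=(dpi, dpi), resolutionunit="INCH",
                         photometric="rgb")

    def test_48bit_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        pixels = rng.integers(0, 65536, (40, 50, 3), dtype=np.uint16)
        p = tmp_path / "scan.tif"
        self._write(p, pixels)
        scan = read_scan(p)
        assert scan.dpi == 150
        assert scan.pixels.shape == (40, 50, 3)
        assert np.array_equal(scan.pixels, pixels)
        assert scan.warnings == []

    def test_8bit_rejected(self, tmp_path):
        p = tmp_path / "scan8.tif"
        self._write(p, np.zeros((10, 10, 3), dtype=np.uint8))
        with pytest.raises(FormatError):
            read_scan(p)

    def test_grayscale_rejected(self, tmp_path):
        p = tmp_path / "gray.tif"
        tifffile.imwrite(p, np.zeros((10, 10), dtype=np.uint16))
        with pytest.raises(FormatError):
            read_scan(p)

    def test_dpi_mismatch_warns_and_uses_file_dpi(self, tmp_path):
        p = tmp_path / "scan300.tif"
        self._write(p, np.zeros((10, 10, 3), dtype=np.uint16), dpi=300)
        scan = read_scan(p, expected_dpi=150)
        assert any("dpi" in w for w in scan.warnings)
        assert scan.dpi == 300
        assert np.isclose(scan.pixel_mm, 25.4 / 300)  # downstream mm scaling from the file


class TestRedChannel:
    def test_bit_identical_and_channel_isolated(self):
        rng = np.random.default_rng(1)
        pixels = rng.integers(0, 65536, (16, 16, 3), dtype=np.uint16)
        scan = FilmScan(pixels=pixels.copy(), dpi=150)
        r = red_channel(scan)
        assert np.array_equal(r, pixels[:, :, 0])
        assert r.dtype == np.uint16
        # altering G/B leaves the extraction unchanged
        pixels2 = pixels.copy()
        pixels2[:, :, 1:] = 0
        assert np.array_equal(red_channel(FilmScan(pixels=pixels2, dpi=150)), r)


class TestOpticalDensity:
    def test_log_identities_and_clipping(self):
        ref = 40000.0
        assert np.allclose(optical_density(np.full((3, 3), ref), ref), 0.0)
        assert np.allclose(optical_density(np.full((3, 3), ref / 10), ref), 1.0)
        # zero pixel value: clipped to 1, finite OD = log10(ref)
        od0 = optical_density(np.zeros((2, 2)), ref)
        assert np.allclose(od0, np.log10(ref))
        with pytest.raises(ArgumentError):
            optical_density(np.ones((2, 2)), 0.0)


class TestNonuniformityCorrection:
    def test_zero_unset_is_identity(self):
        od = np.random.default_rng(2).uniform(0, 1, (8, 8))
        net, n = correct_nonuniformity(od, 0.0)
        assert np.array_equal(net, od)
        assert n == 0

    def test_uniform_subtraction_and_clip_count(self):
        net, n = correct_nonuniformity(np.full((4, 4), 0.5), np.full((4, 4), 0.1))
        assert np.allclose(net, 0.4)
        net2, n2 = correct_nonuniformity(np.full((4, 4), 0.05), 0.1)
        assert np.allclose(net2, 0.0)
        assert n2 == 16

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ArgumentError):
            correct_nonuniformity(np.ones((3, 3)), np.ones((4, 4)))

    @settings(deadline=None, max_examples=25)
    @given(amp=st.floats(0.0, 0.5), tilt=st.floats(-1.0, 1.0))
    def test_scanner_gradient_cancels_exactly(self, amp, tilt):
        # any additive OD field present in both scans leaves net OD unchanged
        yy, xx = np.mgrid[0:20, 0:30]
        gradient = amp * (xx / 29 + tilt * yy / 19)
        signal = 0.2 + 0.3 * np.sin(xx / 5.0)
        net_clean, _ = correct_nonuniformity(signal + 0.05, 0.05)
        net_grad, _ = correct_nonuniformity(signal + 0.05 + gradient, 0.05 + gradient)
        assert np.abs(net_clean - net_grad).max() < 1e-12


class TestRegionReadout:
    def test_uniform_region_any_margin(self):
        od = np.full((50, 60), 0.37)
        region = Rect(5, 5, 40, 30)
        for m in (0.0, 0.2, 0.4):
            assert mean_region_od(od, region, m) == pytest.approx(0.37)

    def test_margin_excludes_contaminated_border(self):
        od = np.zeros((100, 100))
        region = Rect(10, 10, 60, 60)
        core = region.shrunk(0.2)
        od[region.slices] = 9.9  # contaminated
        od[core.slices] = 0.5  # clean core
        # a 20% margin reads only the clean core
        assert mean_region_od(od, region, 0.2) == pytest.approx(0.5)

    def test_extreme_margin_still_defined(self):
        od = np.full((120, 120), 0.2)
        assert mean_region_od(od, Rect(0, 0, 100, 100), 0.49) == pytest.approx(0.2)


class TestCalibrationFit:
    def test_exact_cubic_recovered_from_five_points(self):
        xs = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        doses = 10 * xs + 5 * xs**2 + 2 * xs**3
        curve = fit_calibration(list(zip(xs, doses)))
        assert curve.degree == 3
        assert np.allclose(curve.coeffs, [10, 5, 2], rtol=1e-6)

    def test_three_points_give_exact_constrained_quadratic(self):
        # independent oracle: solve the 2x2 system a1*x + a2*x^2 = D directly
        pts = [(0.0, 0.0), (0.2, 0.5), (0.5, 2.0)]
        a = np.array([[0.2, 0.04], [0.5, 0.25]])
        b = np.array([0.5, 2.0])
        expected = np.linalg.solve(a, b)
        curve = fit_calibration(pts)
        assert curve.degree == 2
        assert np.allclose(curve.coeffs, expected, rtol=1e-9)
        for x, d in pts:
            assert curve(x) == pytest.approx(d, abs=1e-9)

    def test_non_monotone_points_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([(0.0, 0.0), (0.2, 2.0), (0.5, 0.5)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ArgumentError):
            fit_calibration([(0.0, 0.0), (0.5, 2.0)])

    @settings(deadline=None, max_examples=25)
    @given(
        a1=st.floats(1.0, 5.0),
        a2=st.floats(0.0, 3.0),
        a3=st.floats(0.0, 3.0),
    )
    def test_any_monotone_cubic_recovered_from_noise_free_points(self, a1, a2, a3):
        xs = np.array([0.0, 0.12, 0.25, 0.4, 0.55])
        doses = a1 * xs + a2 * xs**2 + a3 * xs**3
        curve = fit_calibration(list(zip(xs, doses)))
        assert np.allclose(curve(xs), doses, rtol=1e-6, atol=1e-9)


class TestApplyCalibration:
    def _curve(self):
        xs = np.array([0.0, 0.15, 0.3, 0.45, 0.6])
        return fit_calibration(list(zip(xs, 3 * xs + 2 * xs**2 + xs**3)))

    def test_zero_od_gives_zero_dose_and_dpi_spacing(self):
        grid, warnings = apply_calibration(self._curve(), np.zeros((4, 4)), dpi=150)
        assert np.allclose(grid.values, 0.0)
        assert grid.spacing[0] == pytest.approx(25.4 / 150)
        assert warnings == []

    def test_forward_inverse_round_trip(self):
        curve = self._curve()
        doses = np.array([0.3, 1.0, 1.9])
        # invert the curve numerically, then convert back
        xs = np.linspace(0, 0.6, 200001)
        ods = np.interp(doses, curve(xs), xs)
        grid, _ = apply_calibration(curve, ods.reshape(1, 3), dpi=150)
        assert np.abs(grid.values.ravel() - doses).max() < 1e-9

    def test_extrapolation_warns(self):
        curve = self._curve()
        _, warnings = apply_calibration(curve, np.full((2, 2), 0.9), dpi=150)
        assert any("extrapolation" in w for w in warnings)


def _plant_marks(n=301, iso=(150.0, 150.0), rotation_deg=0.0, sides=4):
    """Synthetic OD map with Gaussian fiducial blobs near each side."""
    od = np.full((n, n), 0.05)
    fv, fu = np.mgrid[0:n, 0:n]
    theta = np.radians(rotation_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    nominal = [(15.0 - iso[0], 0.0), (n - 16.0 - iso[0], 0.0),
               (0.0, 15.0 - iso[1]), (0.0, n - 16.0 - iso[1])][:sides]
    for mu, mv in nominal:
        mx = iso[0] + cos * mu - sin * mv
        my = iso[1] + sin * mu + cos * mv
        od += 1.2 * np.exp(-((fu - mx) ** 2 + (fv - my) ** 2) / (2 * 2.0**2))
    return od


class TestFiducials:
    def test_symmetric_marks_give_center_and_zero_rotation(self):
        fid = detect_fiducials(_plant_marks())
        assert fid.isocenter == pytest.approx((150.0, 150.0), abs=0.05)
        assert fid.rotation_deg == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize("rot", [-5.0, -2.0, 2.0, 5.0])
    def test_planted_rotation_recovered(self, rot):
        fid = detect_fiducials(_plant_marks(iso=(140.0, 155.0), rotation_deg=rot))
        assert fid.rotation_deg == pytest.approx(rot, abs=0.1)
        assert np.hypot(fid.isocenter[0] - 140.0, fid.isocenter[1] - 155.0) < 0.5

    def test_three_marks_rejected(self):
        with pytest.raises(FiducialDetectionError):
            detect_fiducials(_plant_marks(sides=3))

    def test_ambiguous_band_rejected(self):
        od = _plant_marks()
        # second comparable blob in the left band
        fv, fu = np.mgrid[0:301, 0:301]
        od += 1.2 * np.exp(-((fu - 15.0) ** 2 + (fv - 60.0) ** 2) / (2 * 2.0**2))
        with pytest.raises(FiducialDetectionError):
            detect_fiducials(od)


def _analytic_plane(n=201, spacing=0.5):
    vals = np.zeros((n, n))
    grid = DoseGrid2D(vals, origin=(0, 0), spacing=(spacing, spacing))
    uu, vv = np.meshgrid(grid.u, grid.v)
    f = 1.0 + 0.5 * np.sin(uu / 8.0) * np.cos(vv / 10.0)
    return f, spacing


class TestAlignment:
    def _fid(self, iso_px, rotation):
        marks = np.array([[0, iso_px[1]], [200, iso_px[1]], [iso_px[0], 0], [iso_px[0], 200]])
        return FiducialSet(marks=marks, isocenter=iso_px, rotation_deg=rotation)

    def test_zero_rotation_centered_is_identity(self):
        f, spacing = _analytic_plane()
        plane = DoseGrid2D(f, origin=(0, 0), spacing=(spacing, spacing))
        out = align_to_isocenter(plane, self._fid((100.0, 100.0), 0.0))
        assert np.abs(out.values[out.valid] - plane.values[out.valid]).max() < 1e-9
        # isocenter pixel now at coordinate (0, 0)
        assert out.u[100] == pytest.approx(0.0)
        assert out.v[100] == pytest.approx(0.0)

    @pytest.mark.parametrize("rot", [-5.0, -2.0, 2.0, 5.0])
    def test_rotate_and_restore_round_trip(self, rot):
        n, spacing = 201, 0.5
        c = ((n - 1) / 2 * spacing, (n - 1) / 2 * spacing)
        theta = np.radians(rot)
        grid0 = DoseGrid2D(np.zeros((n, n)), origin=(0, 0), spacing=(spacing, spacing))
        uu, vv = np.meshgrid(grid0.u, grid0.v)
        # film content as scanned: rotated by `rot` about the centre
        qu = np.cos(theta) * (uu - c[0]) + np.sin(theta) * (vv - c[1])
        qv = -np.sin(theta) * (uu - c[0]) + np.cos(theta) * (vv - c[1])
        truth = lambda u, v: 1.0 + 0.5 * np.sin(u / 8.0) * np.cos(v / 10.0)
        rotated = DoseGrid2D(truth(qu, qv), origin=(0, 0), spacing=(spacing, spacing))
        out = align_to_isocenter(rotated, self._fid(((n - 1) / 2, (n - 1) / 2), rot))
        ou, ov = np.meshgrid(out.u, out.v)
        expected = truth(ou, ov)
        interior = out.valid & (np.hypot(ou, ov) < 40)
        # 1% of 2 Gy away from boundaries
        assert np.abs(out.values - expected)[interior].max() < 0.02

    def test_pure_translation_maps_isocenter_to_origin(self):
        plane = DoseGrid2D(np.outer(np.arange(21.0), np.ones(21)), origin=(0, 0), spacing=(1, 1))
        out = align_to_isocenter(plane, self._fid((7.0, 5.0), 0.0))
        assert out.origin == (-7.0, -5.0)
        # value at output coordinate (0,0) equals input value at the isocenter pixel
        assert out.values[5, 7] == pytest.approx(plane.values[5, 7])


class TestLayout:
    def test_json_round_trip(self, tmp_path):
        layout = ScanLayout(
            film=Rect(10, 10, 100, 100),
            subfilms=[(Rect(120, 10, 30, 30), 0.0), (Rect(120, 50, 30, 30), 0.5),
                      (Rect(120, 90, 30, 30), 2.0)],
        )
        p = tmp_path / "layout.json"
        layout.save(p)
        back = ScanLayout.load(p)
        assert back.film == layout.film
        assert back.subfilms == layout.subfilms
        back.validate((200, 200, 3))

    def test_overlapping_rectangles_rejected(self):
        from vaudit.errors import ValidationError

        layout = ScanLayout(
            film=Rect(0, 0, 100, 100),
            subfilms=[(Rect(50, 50, 30, 30), 0.0), (Rect(120, 0, 30, 30), 0.5),
                      (Rect(120, 40, 30, 30), 2.0)],
        )
        with pytest.raises(ValidationError):
            layout.validate((200, 200, 3))
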