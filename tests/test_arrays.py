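"""Array geometries, plan sampling, unwrapping, measured-text dialect."""

import numpy as np
import pytest

from vaudit.arrays import (
    MeasuredSet,
    arccheck_geometry,
    arccheck_plan_plane,
    delta4_geometry,
    delta4_planes,
    read_measured_text,
    sample_at_detectors,
    unwrap_arccheck,
    write_measured_text,
)
from vaudit.dose_model import DoseGrid3D
from vaudit.errors import ArgumentError, OutOfBoundsError, ParseError, ValidationError


class TestArcCheckGeometry:
    def test_all_positions_on_cylinder(self, arccheck):
        r = np.hypot(arccheck.positions[:, 0], arccheck.positions[:, 1])
        assert np.abs(r - arccheck.radius_mm).max() < 1e-6

    def test_consecutive_arc_spacing_is_10mm(self, arccheck):
        # independent recount from the positions themselves: arc length on
        # the cylinder between consecutive diodes
        p = arccheck.positions
        theta = np.arctan2(p[:, 0], p[:, 1])
        dtheta = np.diff(np.unwrap(theta))
        dz = np.diff(p[:, 2])
        arc = np.hypot(arccheck.radius_mm * dtheta, dz)
        assert np.abs(arc - 10.0).max() < 1e-9

    def test_detector_count_matches_independent_walk(self, arccheck):
        # re-walk the helix in 10 mm arc steps with scalar arithmetic
        radius, pitch, length = 104.0, 10.0, 210.0
        rate = np.hypot(radius, pitch / (2 * np.pi))
        n = 0
        theta = 0.0
        while -length / 2 + pitch * theta / (2 * np.pi) <= length / 2 + 1e-9:
            n += 1
            theta += 10.0 / rate
        assert arccheck.n_detectors == n

    def test_axial_extent_and_turn_pitch(self, arccheck):
        z = arccheck.positions[:, 2]
        assert z.min() == pytest.approx(-105.0)
        assert z.max() <= 105.0 + 1e-9
        # one full turn advances one 10 mm pitch
        p = arccheck.positions
        theta = np.unwrap(np.arctan2(p[:, 0], p[:, 1]))
        k = np.argmin(np.abs(theta - (theta[0] + 2 * np.pi)))
        assert p[k, 2] - p[0, 2] == pytest.approx(10.0, abs=0.2)


class TestDelta4Geometry:
    def test_planes_are_orthogonal_and_through_isocenter(self, delta4):
        labels = np.asarray(delta4.plane_labels)
        cor = delta4.positions[labels == "coronal"]
        sag = delta4.positions[labels == "sagittal"]
        assert np.all(cor[:, 1] == 0.0)  # coronal: y = 0
        assert np.all(sag[:, 0] == 0.0)  # sagittal: x = 0
        assert np.dot([0, 1, 0], [1, 0, 0]) == 0  # plane normals orthogonal

    def test_zone_pitches_by_independent_recount(self, delta4):
        labels = np.asarray(delta4.plane_labels)
        cor = delta4.positions[labels == "coronal"][:, [0, 2]]
        from scipy.spatial import cKDTree

        tree = cKDTree(cor)
        dist, _ = tree.query(cor, k=2)
        nn = dist[:, 1]
        central = np.max(np.abs(cor), axis=1) <= 30.0
        deep_outer = np.max(np.abs(cor), axis=1) >= 50.0
        assert np.allclose(nn[central], 5.0)
        assert np.allclose(nn[deep_outer], 10.0)

    def test_boundary_detector_belongs_to_central_zone(self, delta4):
        labels = np.asarray(delta4.plane_labels)
        cor = delta4.positions[labels == "coronal"][:, [0, 2]]
        # (30, 30) is central (inclusive): its 5 mm neighbour (30, 25) exists
        assert any(np.allclose(p, (30.0, 30.0)) for p in cor)
        assert any(np.allclose(p, (30.0, 25.0)) for p in cor)

    def test_shared_axis_detectors_in_exactly_one_plane(self, delta4):
        labels = np.asarray(delta4.plane_labels)
        sag = delta4.positions[labels == "sagittal"]
        # the z-axis line (x=y=0) is carried by the coronal plane only
        assert not np.any((sag[:, 0] == 0.0) & (sag[:, 1] == 0.0))
        cor = delta4.positions[labels == "coronal"]
        on_axis = (cor[:, 0] == 0.0) & (cor[:, 1] == 0.0)
        assert np.count_nonzero(on_axis) > 0


def _linear_grid():
    x = y = z = np.arange(-120, 121, 4.0)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    vals = 3.0 + 0.01 * zz + 0.002 * xx  # strictly positive over the extent
    return DoseGrid3D(vals, origin=(-120.0, -120.0, -120.0), spacing=(4.0, 4.0, 4.0))


class TestSampling:
    def test_constant_grid_samples_constant(self, delta4):
        g = DoseGrid3D(np.full((61, 61, 61), 2.0), origin=(-120, -120, -120), spacing=(4, 4, 4))
        ms = sample_at_detectors(g, delta4)
        assert np.allclose(list(ms.doses.values()), 2.0)

    @pytest.mark.parametrize("device", ["arccheck", "delta4"])
    def test_linear_field_sampled_exactly(self, device, arccheck, delta4):
        geom = arccheck if device == "arccheck" else delta4
        ms = sample_at_detectors(_linear_grid(), geom)
        expected = 3.0 + 0.01 * geom.positions[:, 2] + 0.002 * geom.positions[:, 0]
        got = np.array([ms.doses[i] for i in geom.ids])
        assert np.abs(got - expected).max() < 1e-9

    def test_detectors_outside_grid_reported_by_id(self, arccheck):
        small = DoseGrid3D(np.ones((11, 11, 11)), origin=(-10, -10, -10), spacing=(2, 2, 2))
        with pytest.raises(OutOfBoundsError) as exc:
            sample_at_detectors(small, arccheck)
        assert "AC" in str(exc.value)


class TestUnwrap:
    def test_count_and_doses_preserved(self, arccheck):
        ms = sample_at_detectors(_linear_grid(), arccheck)
        pos, doses = unwrap_arccheck(ms, arccheck)
        assert len(pos) == arccheck.n_detectors
        assert np.array_equal(doses, ms.dose_array(arccheck))

    def test_unwrap_is_isometric_away_from_seam(self, arccheck):
        pos, _ = unwrap_arccheck(sample_at_detectors(_linear_grid(), arccheck), arccheck)
        d_unwrap = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
        circ = 2 * np.pi * arccheck.radius_mm
        not_seam = np.abs(np.diff(pos[:, 0])) < circ / 2
        assert np.abs(d_unwrap[not_seam] - 10.0).max() < 1e-6

    def test_device_mismatch_rejected(self, arccheck, delta4):
        ms = sample_at_detectors(_linear_grid(), delta4)
        with pytest.raises(ArgumentError):
            unwrap_arccheck(ms, arccheck)

    def test_plan_plane_matches_direct_sampling(self, arccheck):
        # for a field depending only on z, the dose read off the unwrapped
        # plan plane at each diode's unwrap coordinate equals the 3-D sample
        # at the diode position (no angular dependence, interpolation exact)
        grid = _linear_grid()
        field_z = DoseGrid3D(
            np.broadcast_to((3.0 + 0.01 * grid.z)[:, None, None], grid.values.shape).copy(),
            origin=grid.origin,
            spacing=grid.spacing,
        )
        plane_z = arccheck_plan_plane(field_z, arccheck, spacing_mm=1.0)
        ms = sample_at_detectors(field_z, arccheck)
        pos, doses = unwrap_arccheck(ms, arccheck)
        from scipy.interpolate import RegularGridInterpolator

        interp_z = RegularGridInterpolator(
            (plane_z.v, plane_z.u), plane_z.values, bounds_error=False, fill_value=None
        )
        assert np.abs(interp_z(pos[:, ::-1]) - doses).max() < 1e-9


class TestDelta4Planes:
    def test_partition_exhaustive_disjoint_doses_unchanged(self, delta4):
        ms = sample_at_detectors(_linear_grid(), delta4)
        planes = delta4_planes(ms, delta4)
        n = sum(len(d) for _, d in planes.values())
        assert n == delta4.n_detectors
        all_doses = np.concatenate([d for _, d in planes.values()])
        assert np.isclose(np.sort(all_doses), np.sort(ms.dose_array(delta4))).all()

    def test_device_mismatch_rejected(self, arccheck, delta4):
        ms = sample_at_detectors(_linear_grid(), arccheck)
        with pytest.raises(ArgumentError):
            delta4_planes(ms, delta4)


class TestMeasuredText:
    def test_round_trip(self, tmp_path, delta4):
        ms = sample_at_detectors(_linear_grid(), delta4)
        ms.metadata["note"] = "unit test"
        p = tmp_path / "m.txt"
        write_measured_text(p, ms)
        back = read_measured_text(p, "delta4", geometry=delta4)
        assert back.device == "delta4"
        assert back.metadata["note"] == "unit test"
        got = back.dose_array(delta4)
        want = ms.dose_array(delta4)
        assert np.abs(got - want).max() < 1e-6  # 6-decimal text quantum

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("# device: arccheck\nAC0000\t1.0\nAC0001\tnotanumber\n")
        with pytest.raises(ParseError) as exc:
            read_measured_text(p, "arccheck")
        assert exc.value.line_number == 3

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.txt"
        p.write_text("# device: arccheck\nAC0000\t1.0\nAC0000\t1.1\n")
        with pytest.raises(ValidationError):
            read_measured_text(p, "arccheck")

    def test_unknown_id_rejected(self, tmp_path):
        p = tmp_path / "unk.txt"
        p.write_text("# device: arccheck\nZZ9999\t1.0\n")
        with pytest.raises(ValidationError):
            read_measured_text(p, "arccheck")

    def test_device_mismatch_rejected(self, tmp_path, delta4):
        ms = sample_at_detectors(_linear_grid(), delta4)
        p = tmp_path / "d4.txt"
        write_measured_text(p, ms)
        with pytest.raises(ValidationError):
            read_measured_text(p, "arccheck")

    def test_negative_dose_rejected(self):
        with pytest.raises(ArgumentError):
            MeasuredSet(device="delta4", doses={"C0000": -0.1})
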