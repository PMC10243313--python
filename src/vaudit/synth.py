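"""Seeded generator of every input the audit consumes.

No institutional audit data are deposited anywhere, so the package ships a
generator that emulates the full submission: an analytic C-shaped planned
dose grid written as DICOM RT Dose / RT Plan, a composite film scan (48-bit
TIFF with calibration subfilms, fiducial marks and film-base density), and
array-detector measurement files in the package's text dialect.

A :class:`Scenario` pins the seed, the grid, the film response truth, the
noise levels and one optional planted delivery error:

* ``subfilm_overdose`` — the 2 Gy calibration subfilm is actually exposed
  to a higher dose while the layout still declares 2 Gy (the real-world
  failure mode this audit design is meant to catch);
* ``dose_scale`` — a global output error on the measured side;
* ``shift`` / ``rotation`` — setup errors of the measured distribution.

Every writer draws from named, seeded generators: a fixed seed reproduces
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian
from scipy.interpolate import RegularGridInterpolator

from .arrays import DetectorGeometry, MeasuredSet, sample_at_detectors, write_measured_text
from .dose_model import DoseGrid2D, DoseGrid3D, PlanInfo
from .errors import ArgumentError
from .film import Rect, ScanLayout

__all__ = [
    "GridSpec",
    "Scenario",
    "make_c_shape_dose",
    "write_rt_files",
    "make_film_scan",
    "make_array_measurement",
    "true_od_of_dose",
]

_UID_ROOT = "1.2.826.0.1.3680043.10.1463."


@dataclass(frozen=True)
class GridSpec:
    """Extent (half-widths, mm) and voxel pitch of the synthetic dose grid."""

    half_extent_mm: tuple[float, float, float] = (115.0, 115.0, 115.0)
    spacing_mm: float = 2.5


@dataclass
class Scenario:
    """Study conditions for one synthetic audit dataset.

    Defaults describe an error-free submission: 2 Gy per-fraction plateau,
    0.5% multiplicative film-pixel noise, 0.005 Gy additive detector noise.
    ``calibration_truth`` are the coefficients (x, x^2, x^3) of the film's
    true monotone dose response against net OD: gently superlinear with
    about 0.54 net OD at 2 Gy, the shape of radiochromic film read on the
    red channel below ~3 Gy.
    """

    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    calibration_truth: tuple[float, float, float] = (3.0, 1.0, 0.5)
    film_noise_frac: float = 0.005  # multiplicative Gaussian sigma on pixel values
    detector_noise_gy: float = 0.005  # additive Gaussian sigma on diode doses
    base_od: float = 0.05  # unexposed film-base optical density
    # planted errors (all "off" by default)
    subfilm_actual_gy: float | None = None  # true dose of the patch labelled 2 Gy
    dose_scale: float = 1.0
    shift_mm: tuple[float, float] = (0.0, 0.0)  # in-plane (u, v) measured-side shift
    rotation_deg: float = 0.0  # film rotation on the scanner bed
    iso_offset_mm: tuple[float, float] = (0.0, 0.0)  # film isocenter offset from film centre
    include_unset: bool = True
    scanner_gradient_od: float = 0.02  # peak-to-peak additive scanner OD non-uniformity
    # 100 mm film leaves the fiducial edge bands clear of the 30 mm-radius target
    film_size_mm: float = 100.0
    film_dpi: float = 150.0

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), int(stream)])


# ---------------------------------------------------------------------------
# planned dose field
# ---------------------------------------------------------------------------

_C_R_IN = 10.0  # mm, inner radius of the C (avoidance core boundary)
_C_R_OUT = 30.0  # mm, outer radius
_C_HALF_ARC = np.radians(135.0)  # 270 degree arc
_C_BISECTOR = np.radians(-90.0)  # gap opens toward +y (the avoidance side)
_C_HALF_Z = 25.0  # mm, axial half-length of the target slab
_SIGMA_NEAR = 5.0  # mm, sharp lateral falloff
_SIGMA_FAR = 60.0  # mm, long-range scatter tail
_FAR_WEIGHT = 0.2
_PLATEAU_GY = 2.0  # single delivered fraction
# transit/entrance dose bath: strongest near the phantom surface (the
# ArcCHECK diode radius), decaying with depth, so cylinder-surface doses sit
# at the realistic ~1 Gy level for a 2 Gy plan
_BATH_GY = 0.8
_BATH_RADIUS = 104.0  # mm, reference surface radius
_BATH_DEPTH_MM = 45.0  # exponential depth constant
_BATH_HALF_Z = 30.0  # mm, axial half-length of the irradiated band
_BATH_SIGMA_Z = 45.0  # mm, axial falloff beyond the band


def _c_distance(x, y, z):
    """Distance (mm) from each point to the C-shaped target region."""
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    dphi = np.angle(np.exp(1j * (phi - _C_BISECTOR)))
    inside_arc = np.abs(dphi) <= _C_HALF_ARC
    d_radial = np.maximum.reduce([_C_R_IN - r, r - _C_R_OUT, np.zeros_like(r)])

    # outside the arc: distance to the two radial end-cap segments
    d_caps = np.full_like(r, np.inf)
    for sign in (+1.0, -1.0):
        ang = _C_BISECTOR + sign * _C_HALF_ARC
        ex, ey = np.cos(ang), np.sin(ang)
        t = np.clip(x * ex + y * ey, _C_R_IN, _C_R_OUT)  # projection onto the cap ray
        d_caps = np.minimum(d_caps, np.hypot(x - t * ex, y - t * ey))

    d_inplane = np.where(inside_arc, d_radial, d_caps)
    dz = np.maximum(np.abs(z) - _C_HALF_Z, 0.0)
    return np.hypot(d_inplane, dz)


def c_shape_dose_at(x, y, z) -> np.ndarray:
    """Analytic per-fraction dose (Gy) of the synthetic C-shaped plan.

    A 2 Gy plateau on the target with a sharp near falloff and a weak
    scatter tail, plus a transit-dose bath peaking near the phantom surface
    and decaying with depth — the component that puts measurable dose
    (~1 Gy) on the ArcCHECK cylinder, while the modulated avoidance core
    stays below 60% of the plateau.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    d = _c_distance(x, y, z)
    near = np.exp(-(d**2) / (2 * _SIGMA_NEAR**2))
    far = np.exp(-(d**2) / (2 * _SIGMA_FAR**2))
    target = _PLATEAU_GY * ((1 - _FAR_WEIGHT) * near + _FAR_WEIGHT * far)

    r = np.hypot(x, y)
    dz = np.maximum(np.abs(z) - _BATH_HALF_Z, 0.0)
    bath = (
        _BATH_GY
        * np.exp(-np.abs(_BATH_RADIUS - r) / _BATH_DEPTH_MM)
        * np.exp(-(dz**2) / (2 * _BATH_SIGMA_Z**2))
    )
    return target + bath


def make_c_shape_dose(scenario: Scenario) -> tuple[DoseGrid3D, PlanInfo]:
    """Build the planned dose grid and plan facts for a scenario.

    The plateau is the 2 Gy single fraction of a 20 Gy / 10 fraction
    prescription; the global maximum stays below 110% of 2 Gy and the dose
    on the avoidance-core axis below 60%, mirroring the audit plan's
    dose-volume constraints.  Isocenter sits at the grid centre.
    """
    hx, hy, hz = scenario.grid.half_extent_mm
    s = scenario.grid.spacing_mm
    if hx < _C_R_OUT + s or hy < _C_R_OUT + s or hz < s:
        raise ArgumentError("grid too small to contain the C-shaped target")
    x = np.arange(-hx, hx + 1e-9, s)
    y = np.arange(-hy, hy + 1e-9, s)
    z = np.arange(-hz, hz + 1e-9, s)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    values = c_shape_dose_at(xx, yy, zz)
    grid = DoseGrid3D(values, origin=(float(x[0]), float(y[0]), float(z[0])), spacing=(s, s, s))
    plan = PlanInfo(
        isocenter=(0.0, 0.0, 0.0),
        n_fractions=10,
        prescription_dose=20.0,
        machine="synthetic-linac",
        tps="vaudit-synth",
    )
    return grid, plan


# ---------------------------------------------------------------------------
# DICOM writers (independent of dose_model's readers)
# ---------------------------------------------------------------------------


def _file_dataset(sop_class_uid: str, seed: int, tag: int) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    # deterministic UIDs so fixed seeds give byte-identical files
    meta.MediaStorageSOPInstanceUID = f"{_UID_ROOT}{seed % (2**31)}.{tag}"
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = f"{_UID_ROOT}{seed % (2**31)}.1"
    ds.SeriesInstanceUID = f"{_UID_ROOT}{seed % (2**31)}.2.{tag}"
    ds.PatientName = "AUDIT^PHANTOM"
    ds.PatientID = "VAUDIT"
    ds.StudyDate = "20230101"
    ds.StudyTime = "000000"
    ds.ContentDate = "20230101"
    ds.ContentTime = "000000"
    return ds


def write_rt_files(grid: DoseGrid3D, plan_info: PlanInfo, out_dir, seed: int = 0):
    """Write standards-conformant RT Dose + RT Plan files for a grid.

    Doses are stored as 16-bit integers with a grid scaling chosen so the
    maximum stays within range; frame offsets are uniform.  Returns
    ``(dose_path, plan_path)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ds = _file_dataset("1.2.840.10008.5.1.4.1.1.481.2", seed, 10)
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nz, ny, nx = grid.values.shape
    peak = float(grid.values.max())
    scaling = peak / 60000.0 if peak > 0 else 1e-6
    stored = np.round(grid.values / scaling).astype(np.uint16)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # (row=dy, col=dx)
    ds.ImagePositionPatient = list(grid.origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(i * grid.spacing[2]) for i in range(nz)]
    ds.DoseGridScaling = scaling
    ds.PixelData = stored.tobytes()
    dose_path = out_dir / "rtdose.dcm"
    ds.save_as(dose_path, enforce_file_format=True)

    pl = _file_dataset("1.2.840.10008.5.1.4.1.1.481.5", seed, 20)
    pl.Modality = "RTPLAN"
    pl.RTPlanLabel = "VAUDIT-CSHAPE"
    pl.RTPlanDate = "20230101"
    pl.RTPlanTime = "000000"
    pl.ManufacturerModelName = plan_info.machine
    pl.Manufacturer = plan_info.tps
    cp = Dataset()
    cp.ControlPointIndex = 0
    cp.IsocenterPosition = list(plan_info.isocenter)
    beam = Dataset()
    beam.BeamNumber = 1
    beam.BeamName = "B1"
    beam.ControlPointSequence = [cp]
    pl.BeamSequence = [beam]
    if plan_info.n_fractions is not None:
        fg = Dataset()
        fg.FractionGroupNumber = 1
        fg.NumberOfFractionsPlanned = plan_info.n_fractions
        pl.FractionGroupSequence = [fg]
    if plan_info.prescription_dose is not None:
        dr = Dataset()
        dr.DoseReferenceNumber = 1
        dr.DoseReferenceStructureType = "SITE"
        dr.DoseReferenceType = "TARGET"
        dr.TargetPrescriptionDose = plan_info.prescription_dose
        pl.DoseReferenceSequence = [dr]
    plan_path = out_dir / "rtplan.dcm"
    pl.save_as(plan_path, enforce_file_format=True)
    return str(dose_path), str(plan_path)


# ---------------------------------------------------------------------------
# film forward model
# ---------------------------------------------------------------------------


def _truth_curve(scenario: Scenario):
    a1, a2, a3 = scenario.calibration_truth
    xs = np.linspace(0.0, 1.5, 30001)
    ds = a1 * xs + a2 * xs**2 + a3 * xs**3
    if np.any(np.diff(ds) <= 0):
        raise ArgumentError("calibration truth must be strictly increasing")
    return xs, ds


def true_od_of_dose(dose, scenario: Scenario) -> np.ndarray:
    """Invert the scenario's true film response: net OD producing each dose."""
    xs, ds = _truth_curve(scenario)
    return np.interp(np.asarray(dose, float), ds, xs)


def _pv_from_od(od: np.ndarray, noise: np.ndarray | None) -> np.ndarray:
    pv = 65535.0 * 10.0 ** (-od)
    if noise is not None:
        pv = pv * (1.0 + noise)
    return np.clip(np.round(pv), 1, 65535).astype(np.uint16)


def make_film_scan(dose_plane: DoseGrid2D, scenario: Scenario, out_dir):
    """Compose the 150 dpi 48-bit RGB scan of the irradiated film + subfilms.

    ``dose_plane`` must be in isocenter coordinates (its (0, 0) is the plan
    isocenter).  The irradiated film region renders the plane through the
    inverse of the true film response, rotated/offset per the scenario, with
    four fiducial marks drawn on the cross through the film isocenter.
    Three calibration subfilms (0, 0.5, 2 Gy nominal) are placed beside the
    film; with ``subfilm_actual_gy`` set, the 2 Gy patch is rendered at that
    true dose while the layout keeps declaring 2 Gy.  A separate unset-film
    scan carries the same scanner OD gradient for the non-uniformity
    correction.  Returns ``(tiff_path, layout_path, unset_path_or_None)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    px_mm = 25.4 / scenario.film_dpi
    n_film = int(round(scenario.film_size_mm / px_mm))
    margin = 40
    sub_w = sub_h = 120
    sub_gap = 30
    canvas_h = margin * 2 + n_film
    canvas_w = margin * 2 + n_film + 60 + sub_w
    sub_x = margin + n_film + 60
    film_rect = Rect(margin, margin, n_film, n_film)

    nominal = [0.0, 0.5, 2.0]
    actual = list(nominal)
    if scenario.subfilm_actual_gy is not None:
        actual[2] = float(scenario.subfilm_actual_gy)
    sub_rects = [Rect(sub_x, margin + i * (sub_h + sub_gap), sub_w, sub_h) for i in range(3)]
    layout = ScanLayout(film=film_rect, subfilms=list(zip(sub_rects, nominal)), unset=None)

    # scanner response non-uniformity: smooth additive OD field over the bed
    yy, xx = np.mgrid[0:canvas_h, 0:canvas_w]
    grad = scenario.scanner_gradient_od * (
        (xx / max(canvas_w - 1, 1) - 0.5) + 0.3 * np.sin(np.pi * yy / max(canvas_h - 1, 1))
    )

    od = np.full((canvas_h, canvas_w), scenario.base_od)

    # irradiated film content: sample the aligned plane at q = R(-theta)(p - iso) - shift
    iso_u = (n_film - 1) / 2.0 + scenario.iso_offset_mm[0] / px_mm
    iso_v = (n_film - 1) / 2.0 + scenario.iso_offset_mm[1] / px_mm
    theta = np.radians(scenario.rotation_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    fv, fu = np.mgrid[0:n_film, 0:n_film]
    pu = (fu - iso_u) * px_mm
    pv = (fv - iso_v) * px_mm
    qu = cos * pu + sin * pv - scenario.shift_mm[0]
    qv = -sin * pu + cos * pv - scenario.shift_mm[1]
    interp = RegularGridInterpolator(
        (dose_plane.v, dose_plane.u), dose_plane.values,
        method="linear", bounds_error=False, fill_value=0.0,
    )
    film_dose = interp(np.column_stack([qv.ravel(), qu.ravel()])).reshape(n_film, n_film)
    film_od = true_od_of_dose(np.clip(film_dose, 0.0, None), scenario)

    # fiducial marks: Gaussian OD blobs near each film side on the isocenter
    # cross (drawn at delivery), rotated about the isocenter with the film
    edge_px = 20.0
    nominal = (
        (edge_px - iso_u, 0.0),  # left
        (n_film - 1 - edge_px - iso_u, 0.0),  # right
        (0.0, edge_px - iso_v),  # top
        (0.0, n_film - 1 - edge_px - iso_v),  # bottom
    )
    mark_od = np.zeros((n_film, n_film))
    for mu, mv in nominal:
        mx = iso_u + cos * mu - sin * mv
        my = iso_v + sin * mu + cos * mv
        mark_od += 1.5 * np.exp(-(((fu - mx) ** 2) + (fv - my) ** 2) / (2 * 2.0**2))
    od[film_rect.slices] += film_od + mark_od

    for rect, dose_gy in zip(sub_rects, actual):
        od[rect.slices] += true_od_of_dose(dose_gy, scenario)

    od += grad
    noise = scenario.rng(1).normal(0.0, scenario.film_noise_frac, od.shape) \
        if scenario.film_noise_frac > 0 else None
    pixels = _pv_from_od(od, noise)
    rgb = np.stack([pixels, (pixels * 0.7).astype(np.uint16), (pixels * 0.5).astype(np.uint16)], axis=-1)

    tiff_path = out_dir / "scan.tif"
    tifffile.imwrite(
        tiff_path, rgb, resolution=(scenario.film_dpi, scenario.film_dpi),
        resolutionunit="INCH", photometric="rgb",
    )
    layout_path = out_dir / "layout.json"
    layout.save(layout_path)

    unset_path = None
    if scenario.include_unset:
        unset_od = np.full((canvas_h, canvas_w), scenario.base_od) + grad
        unset_noise = scenario.rng(2).normal(0.0, scenario.film_noise_frac, unset_od.shape) \
            if scenario.film_noise_frac > 0 else None
        unset_rgb_r = _pv_from_od(unset_od, unset_noise)
        unset_rgb = np.stack(
            [unset_rgb_r, (unset_rgb_r * 0.7).astype(np.uint16), (unset_rgb_r * 0.5).astype(np.uint16)],
            axis=-1,
        )
        unset_path = out_dir / "unset.tif"
        tifffile.imwrite(
            unset_path, unset_rgb, resolution=(scenario.film_dpi, scenario.film_dpi),
            resolutionunit="INCH", photometric="rgb",
        )
    return str(tiff_path), str(layout_path), (str(unset_path) if unset_path else None)


# ---------------------------------------------------------------------------
# array measurements
# ---------------------------------------------------------------------------


def make_array_measurement(
    grid: DoseGrid3D, geom: DetectorGeometry, scenario: Scenario, path
) -> str:
    """Write a measured-text file for a detector array.

    Doses are the planned field sampled at the diode positions with the
    scenario's planted dose scaling and in-plane shift applied, plus seeded
    additive noise — i.e. what a correctly (or incorrectly) delivering
    machine would put on the device.
    """
    shifted = DetectorGeometry(
        device=geom.device,
        ids=list(geom.ids),
        positions=geom.positions - np.array([scenario.shift_mm[0], scenario.shift_mm[1], 0.0]),
        radius_mm=geom.radius_mm,
        unwrap=geom.unwrap,
        plane_labels=geom.plane_labels,
    )
    sampled = sample_at_detectors(grid, shifted)
    doses = np.array([sampled.doses[i] for i in geom.ids]) * scenario.dose_scale
    if scenario.detector_noise_gy > 0:
        doses = doses + scenario.rng(3).normal(0.0, scenario.detector_noise_gy, doses.size)
    doses = np.clip(doses, 0.0, None)
    measured = MeasuredSet(
        device=geom.device,
        doses={i: float(d) for i, d in zip(geom.ids, doses)},
        metadata={"seed": str(scenario.seed), "dose_scale": f"{scenario.dose_scale:g}",
                  "shift_mm": f"{scenario.shift_mm[0]:g},{scenario.shift_mm[1]:g}"},
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    write_measured_text(path, measured)
    return str(path)
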