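"""Physical dose-grid containers and DICOM-RT ingestion.

The audit compares an institution's measured dose distribution against the
planned one recalculated on the QA phantom.  The planned side always enters
as a DICOM RT Dose / RT Plan pair; this module reads those files into
axis-aligned grids in the DICOM patient coordinate system (millimetres,
voxel-centre convention) and extracts/resamples the 2-D planes the film and
array pipelines score against.

Doses are absolute Gy for a single delivered fraction throughout; nothing
in the package ever renormalises a distribution ("no dataset scaling").
Interpolation is (bi/tri)linear everywhere so that linear dose fields are
reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pydicom
from scipy.interpolate import RegularGridInterpolator

from .errors import ArgumentError, FormatError, OutOfBoundsError, UnsupportedGeometryError

__all__ = [
    "DoseGrid3D",
    "DoseGrid2D",
    "PlanInfo",
    "read_rt_dose",
    "read_rt_plan",
    "extract_plane",
    "resample_plane",
]

#: in-plane axis labels per orientation: (u axis, v axis) in patient coordinates
PLANE_AXES = {
    "axial": ("x", "y"),
    "coronal": ("x", "z"),
    "sagittal": ("y", "z"),
}


def _check_spacing(spacing) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise ArgumentError(f"spacings must be positive and finite, got {spacing}")
    return spacing


def _check_dose(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ArgumentError("dose values must all be finite")
    if np.any(values < 0):
        raise ArgumentError("dose values must be non-negative (absolute Gy)")
    return values


@dataclass
class DoseGrid3D:
    """Absorbed dose on a regular axis-aligned 3-D grid.

    ``values[iz, iy, ix]`` is the dose (Gy) at patient-coordinate position
    ``origin + (ix*dx, iy*dy, iz*dz)`` — voxel centres, millimetres.  Axis
    orientation follows the DICOM patient system: +x right→left,
    +y anterior→posterior, +z inferior→superior.
    """

    values: np.ndarray  # (nz, ny, nx), Gy
    origin: tuple[float, float, float]  # (x0, y0, z0) mm, centre of voxel [0,0,0]
    spacing: tuple[float, float, float]  # (dx, dy, dz) mm
    axis_labels: tuple[str, str, str] = ("right-left", "anterior-posterior", "inferior-superior")

    def __post_init__(self):
        self.values = _check_dose(self.values)
        if self.values.ndim != 3:
            raise ArgumentError("DoseGrid3D.values must be 3-D (nz, ny, nx)")
        self.spacing = tuple(float(s) for s in _check_spacing(self.spacing))
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.values.shape[2])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.values.shape[1])

    @property
    def z(self) -> np.ndarray:
        return self.origin[2] + self.spacing[2] * np.arange(self.values.shape[0])

    def interpolator(self) -> RegularGridInterpolator:
        """Trilinear interpolator over (z, y, x) positions in mm."""
        return RegularGridInterpolator(
            (self.z, self.y, self.x), self.values, method="linear", bounds_error=True
        )


@dataclass
class DoseGrid2D:
    """A 2-D dose plane with physical in-plane geometry.

    ``values[iv, iu]`` is the dose at in-plane position
    ``(u0 + iu*du, v0 + iv*dv)`` mm.  ``orientation`` names the plane
    (axial / coronal / sagittal / unwrapped-cylinder / film) and
    ``out_of_plane`` its fixed third coordinate where meaningful.
    ``valid`` marks pixels carrying data (False e.g. outside the support of
    a rotated film); invalid pixels are excluded from all statistics.
    """

    values: np.ndarray  # (nv, nu), Gy
    origin: tuple[float, float]  # (u0, v0) mm
    spacing: tuple[float, float]  # (du, dv) mm
    orientation: str = "axial"
    out_of_plane: float = 0.0
    valid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = _check_dose(self.values)
        if self.values.ndim != 2:
            raise ArgumentError("DoseGrid2D.values must be 2-D (nv, nu)")
        self.spacing = tuple(float(s) for s in _check_spacing(self.spacing))
        self.origin = tuple(float(v) for v in self.origin)
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ArgumentError("valid mask shape must match values")

    @property
    def u(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.values.shape[1])

    @property
    def v(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.values.shape[0])

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (positions (N,2) mm, doses (N,) Gy) of the valid pixels."""
        uu, vv = np.meshgrid(self.u, self.v)
        mask = np.ones(self.values.shape, bool) if self.valid is None else self.valid
        pos = np.column_stack([uu[mask], vv[mask]])
        return pos, self.values[mask]

    def recentered(self, center_u: float, center_v: float) -> "DoseGrid2D":
        """Same plane with in-plane coordinates measured from ``center``."""
        return DoseGrid2D(
            self.values,
            (self.origin[0] - center_u, self.origin[1] - center_v),
            self.spacing,
            orientation=self.orientation,
            out_of_plane=self.out_of_plane,
            valid=self.valid,
        )


@dataclass
class PlanInfo:
    """Plan-level facts the audit checks: isocenter, fractionation, prescription."""

    isocenter: tuple[float, float, float]  # mm, patient coordinates
    n_fractions: int | None = None
    prescription_dose: float | None = None  # total prescription, Gy
    machine: str = ""
    tps: str = ""

    def __post_init__(self):
        if self.n_fractions is not None and self.n_fractions < 1:
            raise ArgumentError("n_fractions must be >= 1")
        if self.prescription_dose is not None and self.prescription_dose <= 0:
            raise ArgumentError("prescription_dose must be positive")


def read_rt_dose(path) -> DoseGrid3D:
    """Read a DICOM RT Dose file into a :class:`DoseGrid3D` (absolute Gy).

    Stored integer pixels are scaled by ``DoseGridScaling``; grid geometry is
    recovered from ``ImagePositionPatient``, ``PixelSpacing`` and the
    ``GridFrameOffsetVector``.  Only axis-aligned grids with uniform frame
    offsets are supported — the audit phantoms are scanned axis-aligned.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{path}: not an RT Dose object (Modality={getattr(ds, 'Modality', None)!r})")
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise FormatError(f"{path}: RT Dose lacks DoseGridScaling")

    iop = [float(v) for v in getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])]
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise UnsupportedGeometryError(
            f"{path}: oblique ImageOrientationPatient {iop} not supported"
        )

    offsets = np.atleast_1d(np.asarray(ds.GridFrameOffsetVector, dtype=float))
    if len(offsets) != int(ds.NumberOfFrames):
        raise FormatError(f"{path}: GridFrameOffsetVector length != NumberOfFrames")
    if len(offsets) > 1:
        steps = np.diff(offsets)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-6):
            raise UnsupportedGeometryError(
                f"{path}: non-uniform frame offsets {offsets.tolist()} not supported"
            )
        dz = float(steps[0])
    else:
        dz = 1.0  # single frame: nominal unit thickness

    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)  # (dy, dx)
    x0, y0, z0 = (float(v) for v in ds.ImagePositionPatient)
    values = ds.pixel_array.astype(np.float64) * float(scaling)
    if values.ndim == 2:
        values = values[None]
    return DoseGrid3D(values, origin=(x0, y0, z0 + offsets[0]), spacing=(col_spacing, row_spacing, dz))


def read_rt_plan(path) -> PlanInfo:
    """Read isocenter, fractionation and prescription from a DICOM RT Plan.

    Fraction count and prescription are optional in the standard; when a file
    omits them the corresponding fields are ``None`` (flagged absent) rather
    than raising.  A plan with no beam isocenter is unusable for registration
    and is rejected.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise FormatError(f"{path}: not an RT Plan object (Modality={getattr(ds, 'Modality', None)!r})")

    isocenter = None
    for beam in getattr(ds, "BeamSequence", []):
        for cp in getattr(beam, "ControlPointSequence", []):
            iso = getattr(cp, "IsocenterPosition", None)
            if iso is not None:
                isocenter = tuple(float(v) for v in iso)
                break
        if isocenter is not None:
            break
    if isocenter is None:
        raise FormatError(f"{path}: no beam isocenter found in RT Plan")

    n_fractions = None
    for fg in getattr(ds, "FractionGroupSequence", []):
        nf = getattr(fg, "NumberOfFractionsPlanned", None)
        if nf is not None:
            n_fractions = int(nf)
            break

    prescription = None
    for dr in getattr(ds, "DoseReferenceSequence", []):
        td = getattr(dr, "TargetPrescriptionDose", None)
        if td is not None:
            prescription = float(td)
            break

    return PlanInfo(
        isocenter=isocenter,
        n_fractions=n_fractions,
        prescription_dose=prescription,
        machine=str(getattr(ds, "ManufacturerModelName", "") or ""),
        tps=str(getattr(ds, "Manufacturer", "") or ""),
    )


def extract_plane(grid: DoseGrid3D, orientation: str, coordinate: float) -> DoseGrid2D:
    """Sample an axial / coronal / sagittal plane at a fixed patient coordinate.

    The plane keeps the grid's in-plane geometry; along the fixed axis the
    dose is linearly interpolated between the two bracketing slices when the
    coordinate is not on a voxel centre.
    """
    if orientation not in PLANE_AXES:
        raise ArgumentError(f"orientation must be one of {sorted(PLANE_AXES)}, got {orientation!r}")

    # axis index in (z, y, x) value order for the fixed coordinate
    fixed = {"axial": 0, "coronal": 1, "sagittal": 2}[orientation]
    axes = (grid.z, grid.y, grid.x)
    coords = axes[fixed]
    if not (coords[0] - 1e-9 <= coordinate <= coords[-1] + 1e-9):
        raise OutOfBoundsError(
            f"coordinate {coordinate} mm outside grid extent [{coords[0]}, {coords[-1]}] along {orientation} axis"
        )

    t = (coordinate - coords[0]) / (coords[1] - coords[0]) if len(coords) > 1 else 0.0
    i0 = int(np.clip(np.floor(t), 0, len(coords) - 2)) if len(coords) > 1 else 0
    frac = t - i0

    take = [slice(None)] * 3
    take[fixed] = i0
    lo = grid.values[tuple(take)]
    if frac > 1e-12 and len(coords) > 1:
        take[fixed] = i0 + 1
        hi = grid.values[tuple(take)]
        plane = (1 - frac) * lo + frac * hi
    else:
        plane = lo.copy()

    if orientation == "axial":  # values[iy, ix] -> (u=x, v=y)
        vals = plane
        origin = (grid.origin[0], grid.origin[1])
        spacing = (grid.spacing[0], grid.spacing[1])
    elif orientation == "coronal":  # values[iz, ix] -> (u=x, v=z)
        vals = plane
        origin = (grid.origin[0], grid.origin[2])
        spacing = (grid.spacing[0], grid.spacing[2])
    else:  # sagittal: values[iz, iy] -> (u=y, v=z)
        vals = plane
        origin = (grid.origin[1], grid.origin[2])
        spacing = (grid.spacing[1], grid.spacing[2])

    # clip tiny negative round-off from interpolation of non-negative data
    vals = np.clip(vals, 0.0, None)
    return DoseGrid2D(vals, origin, spacing, orientation=orientation, out_of_plane=float(coordinate))


def resample_plane(plane: DoseGrid2D, new_spacing: float | tuple[float, float]) -> DoseGrid2D:
    """Bilinearly resample a plane onto a new pixel pitch over the same extent.

    The new lattice starts at the plane's origin corner with the requested
    pitch; when the extent is an integer multiple of the pitch the far corner
    is reproduced as well.  Bilinear interpolation is exact on linear fields.
    """
    if np.isscalar(new_spacing):
        new_spacing = (float(new_spacing), float(new_spacing))
    new_spacing = tuple(float(s) for s in _check_spacing(new_spacing))

    u, v = plane.u, plane.v
    nu = int(np.floor((u[-1] - u[0]) / new_spacing[0] + 1e-9)) + 1
    nv = int(np.floor((v[-1] - v[0]) / new_spacing[1] + 1e-9)) + 1
    new_u = u[0] + new_spacing[0] * np.arange(nu)
    new_v = v[0] + new_spacing[1] * np.arange(nv)

    interp = RegularGridInterpolator((v, u), plane.values, method="linear", bounds_error=False, fill_value=None)
    vv, uu = np.meshgrid(new_v, new_u, indexing="ij")
    vals = interp(np.column_stack([vv.ravel(), uu.ravel()])).reshape(nv, nu)
    vals = np.clip(vals, 0.0, None)
    return DoseGrid2D(
        vals,
        (float(new_u[0]), float(new_v[0])),
        new_spacing,
        orientation=plane.orientation,
        out_of_plane=plane.out_of_plane,
    )
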