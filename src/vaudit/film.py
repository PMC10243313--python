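"""Radiochromic-film pipeline: composite scan to absolute 2-D dose.

An audited institution submits one flatbed scan (150 dpi, 48-bit RGB TIFF)
containing the irradiated film plus at least three calibration subfilms
exposed at known doses (0, 0.5 and 2 Gy), and optionally a scan of an
unexposed ("unset") film.  This module turns that scan into a dose plane
registered to the plan isocenter:

1. red-channel extraction — verbatim, no smoothing or filtering;
2. optical density OD = -log10(PV / PV_white);
3. scanner non-uniformity correction by subtracting the unset-film OD;
4. calibration-curve fit: origin-constrained polynomial (degree up to 3)
   of dose against net OD, fitted to the subfilm readouts;
5. dose conversion and fiducial-based registration: four edge marks give
   the isocenter and the film rotation, which is resampled away.

Doses are absolute Gy; the pipeline never rescales a distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from .dose_model import DoseGrid2D
from .errors import (
    ArgumentError,
    CalibrationError,
    FiducialDetectionError,
    FormatError,
    ValidationError,
)

__all__ = [
    "Rect",
    "FilmScan",
    "ScanLayout",
    "CalibrationCurve",
    "FiducialSet",
    "read_scan",
    "red_channel",
    "optical_density",
    "correct_nonuniformity",
    "mean_region_od",
    "fit_calibration",
    "apply_calibration",
    "detect_fiducials",
    "align_to_isocenter",
]

WHITE_LEVEL = 65535.0  # 16-bit scanner white


@dataclass(frozen=True)
class Rect:
    """Pixel-space rectangle: ``x``/``y`` top-left corner, half-open extent."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ArgumentError(f"rectangle must have positive size, got {self}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)

    def within(self, shape) -> bool:
        h, w = shape[:2]
        return 0 <= self.x and 0 <= self.y and self.x + self.width <= w and self.y + self.height <= h

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x + self.width <= other.x
            or other.x + other.width <= self.x
            or self.y + self.height <= other.y
            or other.y + other.height <= self.y
        )

    def shrunk(self, margin_fraction: float) -> "Rect":
        mx = int(round(self.width * margin_fraction))
        my = int(round(self.height * margin_fraction))
        return Rect(self.x + mx, self.y + my, self.width - 2 * mx, self.height - 2 * my)

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(int(d["x"]), int(d["y"]), int(d["width"]), int(d["height"]))


@dataclass
class FilmScan:
    """A 48-bit RGB film scan: per-channel 16-bit pixel data plus scan dpi."""

    pixels: np.ndarray  # (H, W, 3) uint16
    dpi: float
    channel_labels: tuple[str, str, str] = ("R", "G", "B")
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError("FilmScan.pixels must be (H, W, 3) RGB")
        if self.pixels.dtype != np.uint16:
            raise FormatError(f"FilmScan requires 16 bits/channel, got dtype {self.pixels.dtype}")
        if self.dpi <= 0:
            raise ArgumentError("dpi must be positive")

    @property
    def pixel_mm(self) -> float:
        return 25.4 / self.dpi


@dataclass
class ScanLayout:
    """Where things sit on the composite scan, in pixels.

    ``subfilms`` maps each calibration patch to its nominal dose (Gy).  At
    least three subfilms are required, one of them at 0 Gy; rectangles must
    lie inside the image and be pairwise disjoint.
    """

    film: Rect
    subfilms: list[tuple[Rect, float]]
    unset: Rect | None = None

    def validate(self, image_shape) -> None:
        rects = [self.film] + [r for r, _ in self.subfilms] + ([self.unset] if self.unset else [])
        for r in rects:
            if not r.within(image_shape):
                raise ValidationError(f"layout rectangle {r} outside image bounds {image_shape[:2]}")
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if rects[i].overlaps(rects[j]):
                    raise ValidationError(f"layout rectangles overlap: {rects[i]} / {rects[j]}")
        doses = [d for _, d in self.subfilms]
        if len(self.subfilms) < 3:
            raise ValidationError("at least 3 calibration subfilms are required")
        if any(d < 0 for d in doses):
            raise ValidationError("subfilm nominal doses must be >= 0")
        if not any(d == 0 for d in doses):
            raise ValidationError("a 0 Gy subfilm is required (anchors the calibration origin)")

    def to_dict(self) -> dict:
        return {
            "film": self.film.to_dict(),
            "subfilms": [{"rect": r.to_dict(), "dose_gy": d} for r, d in self.subfilms],
            "unset": self.unset.to_dict() if self.unset else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanLayout":
        return cls(
            film=Rect.from_dict(d["film"]),
            subfilms=[(Rect.from_dict(s["rect"]), float(s["dose_gy"])) for s in d["subfilms"]],
            unset=Rect.from_dict(d["unset"]) if d.get("unset") else None,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ScanLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CalibrationCurve:
    """Origin-constrained polynomial mapping net OD to dose (Gy).

    ``coeffs[j]`` multiplies ``x**(j+1)`` (no constant term: a 0 Gy subfilm
    pins D(0) = 0).  The curve is guaranteed strictly increasing over
    ``od_range`` at construction time.
    """

    coeffs: np.ndarray  # (degree,) for powers 1..degree
    od_range: tuple[float, float]
    residuals: np.ndarray  # per calibration point, Gy

    def __post_init__(self):
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        self.residuals = np.asarray(self.residuals, dtype=float)

    @property
    def degree(self) -> int:
        return len(self.coeffs)

    def __call__(self, net_od):
        x = np.asarray(net_od, dtype=float)
        full = np.concatenate([self.coeffs[::-1], [0.0]])  # highest power first, D(0)=0
        return np.polyval(full, x)

    def derivative(self, net_od):
        x = np.asarray(net_od, dtype=float)
        powers = np.arange(1, self.degree + 1)
        dcoef = (self.coeffs * powers)[::-1]
        return np.polyval(dcoef, x)


@dataclass
class FiducialSet:
    """Four registration marks (left/right/top/bottom), derived isocenter and
    film rotation.  Coordinates in pixels, ``(x=column, y=row)``."""

    marks: np.ndarray  # (4, 2): left, right, top, bottom
    isocenter: tuple[float, float]  # px
    rotation_deg: float

    def __post_init__(self):
        self.marks = np.asarray(self.marks, dtype=float)
        if self.marks.shape != (4, 2):
            raise ArgumentError("FiducialSet requires exactly 4 marks")
        if abs(self.rotation_deg) > 10.0:
            raise FiducialDetectionError(
                f"implausible film rotation {self.rotation_deg:.2f} deg (sanity bound 10 deg)"
            )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_scan(path, expected_dpi: float = 150.0) -> FilmScan:
    """Read a 48-bit RGB TIFF film scan.

    The dpi comes from the file's resolution tags; a mismatch with
    ``expected_dpi`` is recorded as a warning (downstream mm scaling always
    uses the file's own dpi), while a wrong bit depth or missing colour is a
    hard format error.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        if pixels.ndim != 3 or pixels.shape[-1] != 3:
            raise FormatError(f"{path}: expected RGB scan, got shape {pixels.shape}")
        if pixels.dtype != np.uint16:
            raise FormatError(f"{path}: expected 16 bits/channel (48-bit RGB), got {pixels.dtype}")
        dpi = None
        tags = page.tags
        if "XResolution" in tags:
            num, den = tags["XResolution"].value
            res = num / den
            unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
            unit = getattr(unit, "value", unit)
            if unit == 3:  # centimetre
                res *= 2.54
            dpi = float(res)
    warnings = []
    if dpi is None:
        warnings.append(f"no resolution tag in {path}; assuming {expected_dpi} dpi")
        dpi = float(expected_dpi)
    elif abs(dpi - expected_dpi) > 0.5:
        warnings.append(f"scan dpi {dpi:g} differs from expected {expected_dpi:g}")
    return FilmScan(pixels=pixels, dpi=dpi, warnings=warnings)


def red_channel(scan: FilmScan) -> np.ndarray:
    """The red channel, verbatim — no smoothing, filtering or dtype change.

    Radiochromic film is read out on the red channel where its dose response
    is strongest; the audit deliberately applies no filtering so the gamma
    analysis sees the raw measurement.
    """
    idx = scan.channel_labels.index("R")
    return scan.pixels[:, :, idx].copy()


def optical_density(response: np.ndarray, reference_value: float = WHITE_LEVEL) -> np.ndarray:
    """OD = -log10(PV / reference) elementwise; PV clipped to >= 1 first."""
    if reference_value <= 0:
        raise ArgumentError("reference_value must be positive")
    pv = np.clip(np.asarray(response, dtype=float), 1.0, None)
    return -np.log10(pv / reference_value)


def correct_nonuniformity(od: np.ndarray, unset_od) -> tuple[np.ndarray, int]:
    """Net OD = exposed OD minus the unset-film OD (map or scalar baseline).

    Any additive scanner-response field present in both scans cancels here.
    Negative net OD (sub-base readings, i.e. noise) is clipped to zero;
    the clip count is returned for the audit's warning statistics.
    """
    od = np.asarray(od, dtype=float)
    if np.ndim(unset_od) > 0:
        unset = np.asarray(unset_od, dtype=float)
        if unset.shape != od.shape:
            raise ArgumentError(f"unset OD shape {unset.shape} != exposed OD shape {od.shape}")
    else:
        unset = float(unset_od)
    net = od - unset
    n_clipped = int(np.count_nonzero(net < 0))
    return np.clip(net, 0.0, None), n_clipped


def mean_region_od(od: np.ndarray, region: Rect, margin_fraction: float = 0.2) -> float:
    """Mean OD over the central core of a rectangle (each side shrunk by
    ``margin_fraction``), for subfilm readout away from cut edges."""
    if not 0 <= margin_fraction < 0.5:
        raise ArgumentError("margin_fraction must be in [0, 0.5)")
    if not region.within(od.shape):
        raise ArgumentError(f"region {region} outside OD map of shape {od.shape}")
    core = region.shrunk(margin_fraction)
    if core.width <= 0 or core.height <= 0:
        raise ArgumentError("margin leaves an empty central region")
    return float(np.mean(od[core.slices]))


def fit_calibration(points) -> CalibrationCurve:
    """Least-squares polynomial fit of dose against net OD through the origin.

    The 0 Gy subfilm pins D(0) = 0, so the fitted polynomial has no constant
    term and degree d = min(3, n_points - 1): the canonical three-subfilm
    set {0, 0.5, 2 Gy} yields a constrained quadratic, five or more points
    the full constrained cubic.  A fit that is not strictly increasing over
    the calibrated OD range is rejected — a non-monotone curve cannot be
    inverted and signals corrupted subfilms.
    """
    pts = [(float(x), float(d)) for x, d in points]
    if len(pts) < 3:
        raise ArgumentError(f"calibration needs >= 3 points, got {len(pts)}")
    ods = np.array([x for x, _ in pts])
    doses = np.array([d for _, d in pts])
    if len(np.unique(ods)) < len(ods):
        raise ArgumentError("calibration points must have distinct net OD values")
    if not np.any(doses == 0):
        raise ArgumentError("a 0 Gy calibration point is required")
    if np.any(ods < 0):
        raise ArgumentError("net OD must be non-negative")

    degree = min(3, len(pts) - 1)
    basis = np.vander(ods, degree + 1, increasing=True)[:, 1:]  # x, x^2, ... (no constant)
    coeffs, *_ = np.linalg.lstsq(basis, doses, rcond=None)

    od_max = float(np.max(ods))
    curve = CalibrationCurve(coeffs=coeffs, od_range=(0.0, od_max), residuals=doses - basis @ coeffs)
    xs = np.linspace(0.0, od_max, 512)
    if np.any(curve.derivative(xs) <= 0):
        raise CalibrationError(
            "fitted calibration curve is not strictly increasing over the OD range; "
            "check subfilm doses and readouts"
        )
    return curve


def apply_calibration(
    curve: CalibrationCurve, net_od: np.ndarray, dpi: float
) -> tuple[DoseGrid2D, list[str]]:
    """Convert a net-OD map to an absolute dose plane (Gy).

    Pixel pitch is 25.4/dpi mm.  OD beyond the fitted range is evaluated by
    polynomial extrapolation and reported in the returned warnings.
    """
    if dpi <= 0:
        raise ArgumentError("dpi must be positive")
    net_od = np.asarray(net_od, dtype=float)
    warnings = []
    n_extra = int(np.count_nonzero(net_od > curve.od_range[1] + 1e-12))
    if n_extra:
        warnings.append(
            f"{n_extra} pixels above the calibrated OD range "
            f"(max fitted OD {curve.od_range[1]:.3f}); polynomial extrapolation applied"
        )
    dose = np.clip(curve(net_od), 0.0, None)
    spacing = 25.4 / dpi
    grid = DoseGrid2D(dose, origin=(0.0, 0.0), spacing=(spacing, spacing), orientation="film")
    return grid, warnings


def _band_mark(od: np.ndarray, band: tuple[slice, slice], side: str) -> tuple[float, float]:
    """Locate one fiducial mark inside an edge band.

    Threshold: Otsu within the band, floored at median + 0.1 OD (a bandful
    of background noise is never split into a phantom mark) and at half the
    band's peak density above median — the ink marks are far denser than
    any dose tail that can reach an edge band, so half-peak cleanly
    separates a mark from field penumbra.  The strongest connected blob's
    intensity-weighted centroid is the mark; a second blob within 80% of
    its mass makes the detection ambiguous and is an error — an audit must
    fail loudly rather than guess.
    """
    sub = od[band]
    med = float(np.median(sub))
    floor = max(med + 0.1, med + 0.5 * (float(np.max(sub)) - med))
    try:
        thr = max(float(threshold_otsu(sub)), floor)
    except ValueError:  # constant band
        thr = floor
    mask = sub > thr
    if not np.any(mask):
        raise FiducialDetectionError(f"no fiducial mark found in the {side} edge band")
    labels, n = ndimage.label(mask)
    masses = ndimage.sum_labels(sub - med, labels, index=np.arange(1, n + 1))
    order = np.argsort(masses)[::-1]
    if n > 1 and masses[order[1]] >= 0.8 * masses[order[0]]:
        raise FiducialDetectionError(
            f"ambiguous fiducial in the {side} edge band: two comparable candidates"
        )
    blob = labels == order[0] + 1
    w = np.where(blob, sub - med, 0.0)
    cy, cx = ndimage.center_of_mass(w)
    return float(cx + band[1].start), float(cy + band[0].start)


def detect_fiducials(od: np.ndarray, edge_band_fraction: float = 0.12) -> FiducialSet:
    """Find the four edge marks and derive isocenter and rotation.

    One mark is expected near the middle of each image side, inside a band
    of width ``edge_band_fraction`` x image size.  The isocenter is the
    intersection of the left-right and top-bottom mark lines; the rotation
    is the mean angular deviation of those lines from the image axes.
    """
    od = np.asarray(od, dtype=float)
    h, w = od.shape
    bw = max(2, int(round(w * edge_band_fraction)))
    bh = max(2, int(round(h * edge_band_fraction)))
    left = _band_mark(od, (slice(0, h), slice(0, bw)), "left")
    right = _band_mark(od, (slice(0, h), slice(w - bw, w)), "right")
    top = _band_mark(od, (slice(0, bh), slice(0, w)), "top")
    bottom = _band_mark(od, (slice(h - bh, h), slice(0, w)), "bottom")

    lx, ly = left
    rx, ry = right
    tx, ty = top
    bx, by = bottom

    # intersection of line L-R with line T-B
    p = np.array(left)
    r = np.array(right) - p
    q = np.array(top)
    s = np.array(bottom) - q
    denom = r[0] * s[1] - r[1] * s[0]
    if abs(denom) < 1e-12:
        raise FiducialDetectionError("fiducial lines are parallel; marks implausible")
    t = ((q[0] - p[0]) * s[1] - (q[1] - p[1]) * s[0]) / denom
    iso = p + t * r

    ang_h = np.degrees(np.arctan2(ry - ly, rx - lx))  # deviation from horizontal
    ang_v = np.degrees(np.arctan2(by - ty, bx - tx)) - 90.0  # deviation from vertical
    rotation = (ang_h + ang_v) / 2.0

    return FiducialSet(
        marks=np.array([left, right, top, bottom]),
        isocenter=(float(iso[0]), float(iso[1])),
        rotation_deg=float(rotation),
    )


def align_to_isocenter(dose: DoseGrid2D, fid: FiducialSet) -> DoseGrid2D:
    """Undo the detected film rotation and re-origin the plane on the isocenter.

    The dose plane is resampled (bilinear) on a grid of the same pitch and
    pixel count whose coordinate (0, 0) is the fiducial isocenter; pixels
    that fall outside the original film support are marked invalid and are
    excluded from every downstream statistic.
    """
    theta = np.radians(fid.rotation_deg)
    du, dv = dose.spacing
    cu = dose.origin[0] + fid.isocenter[0] * du
    cv = dose.origin[1] + fid.isocenter[1] * dv

    # output coordinate q (mm, isocenter origin) samples input at c + R(theta) q
    cos, sin = np.cos(theta), np.sin(theta)
    m_vu = np.array([[cos, sin], [-sin, cos]])  # acting on (v, u)
    nv, nu = dose.values.shape
    o_u = -cu + dose.origin[0]
    o_v = -cv + dose.origin[1]
    # input index = (p - origin)/spacing, p = c + M q, q = o + spacing*i
    scale = np.diag([dv, du])
    mat = np.linalg.inv(scale) @ m_vu @ scale
    offset_mm = np.array([cv - dose.origin[1], cu - dose.origin[0]]) + m_vu @ np.array([o_v, o_u])
    offset_idx = offset_mm / np.array([dv, du])

    out = ndimage.affine_transform(
        dose.values, mat, offset=offset_idx, order=1, mode="constant", cval=np.nan,
        output_shape=(nv, nu),
    )
    valid = np.isfinite(out)
    if dose.valid is not None:
        src_valid = ndimage.affine_transform(
            dose.valid.astype(float), mat, offset=offset_idx, order=1, mode="constant", cval=0.0,
            output_shape=(nv, nu),
        )
        valid &= src_valid > 0.999
    return DoseGrid2D(
        np.nan_to_num(out, nan=0.0).clip(0.0, None),
        origin=(o_u, o_v),
        spacing=dose.spacing,
        orientation=dose.orientation,
        out_of_plane=dose.out_of_plane,
        valid=valid,
    )
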