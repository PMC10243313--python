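"""Detector-array geometries and measurement handling.

Two commercial QA arrays are modelled:

* **ArcCHECK** — diodes on a helical lattice wound on a cylinder (radius
  104 mm by default, a vendor constant), 10 mm pitch between turns and
  10 mm arc spacing along the helix.  Analysis happens on the *unwrapped*
  cylinder surface: each diode maps to (arc length, z), an isometry of the
  surface, and the planned dose is sampled on the same unwrapped lattice.
* **Delta4** — diodes in two orthogonal planes through the isocenter
  (modelled as coronal + sagittal), 5 mm pitch inside the central
  60 x 60 mm^2 region (boundary inclusive) and 10 mm outside.

Measured doses travel in a plain tab-separated text dialect defined by this
package (vendor-native exports vary and converters are out of scope):
``#``-prefixed ``key: value`` header lines, one of which must be
``device``, followed by one ``id<TAB>dose_gy`` line per detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dose_model import DoseGrid2D, DoseGrid3D
from .errors import ArgumentError, OutOfBoundsError, ParseError, ValidationError

__all__ = [
    "DetectorGeometry",
    "MeasuredSet",
    "arccheck_geometry",
    "delta4_geometry",
    "sample_at_detectors",
    "unwrap_arccheck",
    "delta4_planes",
    "arccheck_plan_plane",
    "read_measured_text",
    "write_measured_text",
]

ARCCHECK_RADIUS_MM = 104.0  # vendor constant, overridable
ARCCHECK_LENGTH_MM = 210.0


@dataclass
class DetectorGeometry:
    """Diode ids and 3-D positions for one device.

    For ArcCHECK, ``unwrap[i] = (arc length u, axial z)`` in mm with u = 0 at
    the posterior-most column and z = 0 at the isocenter; ``radius_mm`` is
    the cylinder radius.  For Delta4, ``plane_labels[i]`` names the board
    (coronal or sagittal) carrying each diode.
    """

    device: str
    ids: list[str]
    positions: np.ndarray  # (N, 3) mm, patient coordinates
    radius_mm: float | None = None
    unwrap: np.ndarray | None = None  # (N, 2) mm (u, z), arccheck only
    plane_labels: list[str] | None = None  # delta4 only

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ArgumentError("positions must be (N, 3)")
        if len(self.ids) != len(self.positions):
            raise ArgumentError("ids and positions must align")
        if len(set(self.ids)) != len(self.ids):
            raise ArgumentError("detector ids must be unique")
        if self.unwrap is not None:
            self.unwrap = np.asarray(self.unwrap, dtype=float)

    @property
    def n_detectors(self) -> int:
        return len(self.ids)

    def to_dict(self) -> dict:
        return {
            "device": self.device,
            "ids": list(self.ids),
            "positions_mm": self.positions.tolist(),
            "radius_mm": self.radius_mm,
            "unwrap_mm": self.unwrap.tolist() if self.unwrap is not None else None,
            "plane_labels": self.plane_labels,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorGeometry":
        return cls(
            device=d["device"],
            ids=list(d["ids"]),
            positions=np.asarray(d["positions_mm"], dtype=float),
            radius_mm=d.get("radius_mm"),
            unwrap=np.asarray(d["unwrap_mm"], dtype=float) if d.get("unwrap_mm") else None,
            plane_labels=d.get("plane_labels"),
        )


@dataclass
class MeasuredSet:
    """Per-detector measured doses (absolute Gy) plus acquisition metadata."""

    device: str
    doses: dict[str, float]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.doses.items():
            if not np.isfinite(v) or v < 0:
                raise ArgumentError(f"detector {k}: dose must be finite and >= 0, got {v}")

    def dose_array(self, geom: DetectorGeometry) -> np.ndarray:
        """Doses ordered like ``geom.ids``; every geometry id must be present."""
        missing = [i for i in geom.ids if i not in self.doses]
        if missing:
            raise ValidationError(f"measured set lacks {len(missing)} detector ids, e.g. {missing[:3]}")
        return np.array([self.doses[i] for i in geom.ids], dtype=float)


def arccheck_geometry(
    radius_mm: float = ARCCHECK_RADIUS_MM,
    spacing_mm: float = 10.0,
    length_mm: float = ARCCHECK_LENGTH_MM,
) -> DetectorGeometry:
    """Helical diode lattice on a cylinder.

    Walking along the helix advances a constant 10 mm of arc per diode while
    z climbs one 10 mm pitch per turn, so axially adjacent turns are also
    10 mm apart.  theta = 0 points posterior (+y); z = 0 is the isocenter
    plane, diodes spanning z in [-length/2, +length/2].
    """
    if radius_mm <= 0 or spacing_mm <= 0 or length_mm <= 0:
        raise ArgumentError("geometry parameters must be positive")
    pitch = spacing_mm  # axial advance per turn
    # arc length per unit theta along the helix
    helix_rate = np.hypot(radius_mm, pitch / (2 * np.pi))
    dtheta = spacing_mm / helix_rate
    n = int(np.floor(length_mm / pitch * 2 * np.pi / dtheta)) + 1

    theta = dtheta * np.arange(n)
    z = -length_mm / 2.0 + pitch * theta / (2 * np.pi)
    keep = z <= length_mm / 2.0 + 1e-9
    theta, z = theta[keep], z[keep]
    x = radius_mm * np.sin(theta)
    y = radius_mm * np.cos(theta)
    ids = [f"AC{i:04d}" for i in range(len(theta))]
    unwrap = np.column_stack([radius_mm * np.mod(theta, 2 * np.pi), z])
    return DetectorGeometry(
        device="arccheck",
        ids=ids,
        positions=np.column_stack([x, y, z]),
        radius_mm=radius_mm,
        unwrap=unwrap,
    )


def _delta4_coords(central: float = 30.0, outer: float = 100.0) -> np.ndarray:
    inner = np.arange(-central, central + 1e-9, 5.0)
    neg = np.arange(-outer, -central, 10.0)
    pos = np.arange(central + 10.0, outer + 1e-9, 10.0)
    return np.concatenate([neg, inner, pos])


def delta4_geometry() -> DetectorGeometry:
    """Two orthogonal diode planes through the isocenter.

    In each plane the diodes sit at 5 mm pitch where both in-plane
    coordinates are within +/-30 mm (central 60 x 60 mm^2, boundary
    inclusive) and on a 10 mm lattice elsewhere, out to +/-100 mm.
    Diodes on the shared axis line (the z-axis) belong to the coronal
    plane only.
    """
    ids: list[str] = []
    pos: list[tuple[float, float, float]] = []
    labels: list[str] = []

    def plane_points():
        grid10 = np.arange(-100.0, 100.0 + 1e-9, 10.0)
        pts = {(u, v) for u in grid10 for v in grid10 if max(abs(u), abs(v)) > 30.0}
        for u in _delta4_coords():
            for v in _delta4_coords():
                if max(abs(u), abs(v)) <= 30.0:
                    pts.add((u, v))
        return sorted(pts)

    for u, v in plane_points():
        ids.append(f"C{len(ids):04d}")
        pos.append((u, 0.0, v))  # coronal: y = 0, in-plane (x, z)
        labels.append("coronal")
    for u, v in plane_points():
        if u == 0.0:
            continue  # shared z-axis line assigned to the coronal plane
        ids.append(f"S{len(ids):04d}")
        pos.append((0.0, u, v))  # sagittal: x = 0, in-plane (y, z)
        labels.append("sagittal")

    return DetectorGeometry(
        device="delta4", ids=ids, positions=np.asarray(pos), plane_labels=labels
    )


def sample_at_detectors(plan: DoseGrid3D, geom: DetectorGeometry) -> MeasuredSet:
    """Trilinear interpolation of the planned dose at every diode position."""
    interp = plan.interpolator()
    p = geom.positions
    inside = (
        (p[:, 0] >= plan.x[0]) & (p[:, 0] <= plan.x[-1])
        & (p[:, 1] >= plan.y[0]) & (p[:, 1] <= plan.y[-1])
        & (p[:, 2] >= plan.z[0]) & (p[:, 2] <= plan.z[-1])
    )
    if not np.all(inside):
        bad = [geom.ids[i] for i in np.flatnonzero(~inside)]
        raise OutOfBoundsError(
            f"{len(bad)} detectors outside the dose grid, e.g. {bad[:5]}"
        )
    doses = interp(p[:, ::-1])  # interpolator wants (z, y, x)
    doses = np.clip(doses, 0.0, None)
    return MeasuredSet(device=geom.device, doses=dict(zip(geom.ids, doses.tolist())))


def unwrap_arccheck(values: MeasuredSet, geom: DetectorGeometry):
    """Map measured diode doses to the unwrapped-cylinder plane.

    Returns ``(positions (N,2) mm, doses (N,))`` with positions (arc length,
    z); doses are passed through untouched.  Unwrapping is an isometry of
    the cylinder surface except across the seam at arc length 0.
    """
    if values.device != "arccheck" or geom.device != "arccheck":
        raise ArgumentError("unwrap_arccheck requires arccheck measured set and geometry")
    doses = values.dose_array(geom)
    return geom.unwrap.copy(), doses


def delta4_planes(values: MeasuredSet, geom: DetectorGeometry):
    """Partition measured diode doses into the two boards.

    Returns ``{"coronal": (positions (N,2), doses), "sagittal": ...}`` with
    in-plane coordinates (x, z) and (y, z) respectively.  The partition is
    exhaustive and disjoint; z-axis diodes sit in the coronal plane by the
    construction rule of :func:`delta4_geometry`.
    """
    if values.device != "delta4" or geom.device != "delta4":
        raise ArgumentError("delta4_planes requires delta4 measured set and geometry")
    doses = values.dose_array(geom)
    out = {}
    labels = np.asarray(geom.plane_labels)
    for plane, cols in (("coronal", (0, 2)), ("sagittal", (1, 2))):
        sel = labels == plane
        pos = geom.positions[sel][:, cols]
        out[plane] = (pos, doses[sel])
    return out


def arccheck_plan_plane(
    plan: DoseGrid3D,
    geom: DetectorGeometry,
    spacing_mm: float = 1.0,
    wrap_margin_mm: float = 10.0,
    center=(0.0, 0.0, 0.0),
) -> DoseGrid2D:
    """Planned dose sampled on the unwrapped ArcCHECK cylinder surface.

    The lattice covers arc length [-margin, circumference + margin] (the
    margin repeats the cylinder periodically so gamma searches near the
    seam see both sides) and the axial extent of the diodes.  ``center`` is
    the cylinder-axis position in patient coordinates — the phantom is set
    up on the plan isocenter.
    """
    if geom.device != "arccheck":
        raise ArgumentError("arccheck_plan_plane requires an arccheck geometry")
    cx, cy, cz = (float(c) for c in center)
    r = geom.radius_mm
    circ = 2 * np.pi * r
    u = np.arange(-wrap_margin_mm, circ + wrap_margin_mm + 1e-9, spacing_mm)
    z0, z1 = geom.unwrap[:, 1].min(), geom.unwrap[:, 1].max()
    v = np.arange(z0, z1 + 1e-9, spacing_mm)
    theta = np.mod(u / r, 2 * np.pi)
    uu_t, vv = np.meshgrid(theta, v)
    xs = cx + r * np.sin(uu_t)
    ys = cy + r * np.cos(uu_t)
    pts = np.column_stack([cz + vv.ravel(), ys.ravel(), xs.ravel()])  # (z, y, x)
    interp = plan.interpolator()
    vals = np.clip(interp(pts).reshape(len(v), len(u)), 0.0, None)
    return DoseGrid2D(
        vals,
        origin=(float(u[0]), float(v[0])),
        spacing=(spacing_mm, spacing_mm),
        orientation="unwrapped-cylinder",
    )


def write_measured_text(path, measured: MeasuredSet) -> None:
    """Write a measured set in the package's tab-separated dialect."""
    with open(path, "w") as fh:
        fh.write("# vaudit-measured: v1\n")
        fh.write(f"# device: {measured.device}\n")
        for k, v in measured.metadata.items():
            fh.write(f"# {k}: {v}\n")
        for det_id, dose in measured.doses.items():
            fh.write(f"{det_id}\t{dose:.6f}\n")


def read_measured_text(path, device: str, geometry: DetectorGeometry | None = None) -> MeasuredSet:
    """Parse a measured-text file and validate it against the device geometry.

    ``geometry`` defaults to the device's standard build.  Malformed lines
    raise :class:`ParseError` with the line number; duplicate ids or ids not
    in the geometry raise :class:`ValidationError`.
    """
    if device not in ("arccheck", "delta4"):
        raise ArgumentError(f"unknown device {device!r}")
    if geometry is None:
        geometry = arccheck_geometry() if device == "arccheck" else delta4_geometry()
    known = set(geometry.ids)

    doses: dict[str, float] = {}
    metadata: dict[str, str] = {}
    file_device = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    metadata[k.strip()] = v.strip()
                    if k.strip() == "device":
                        file_device = v.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"expected 'id<TAB>dose_gy', got {line!r}", lineno)
            det_id, dose_s = parts[0].strip(), parts[1].strip()
            try:
                dose = float(dose_s)
            except ValueError:
                raise ParseError(f"dose {dose_s!r} is not a number", lineno) from None
            if not np.isfinite(dose) or dose < 0:
                raise ParseError(f"dose {dose} must be finite and >= 0", lineno)
            if det_id in doses:
                raise ValidationError(f"duplicate detector id {det_id!r}")
            if det_id not in known:
                raise ValidationError(f"detector id {det_id!r} not in the {device} geometry")
            doses[det_id] = dose

    if file_device is not None and file_device != device:
        raise ValidationError(f"file declares device {file_device!r}, expected {device!r}")
    if not doses:
        raise ParseError("no detector readings found in file")
    metadata.pop("device", None)
    return MeasuredSet(device=device, doses=doses, metadata=metadata)
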