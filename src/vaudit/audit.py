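"""Audit orchestration: the film and array credentialing workflows.

Each workflow reads the institution's submission, runs the corresponding
measurement pipeline, scores it against the planned dose with the
credentialing gamma preset, and emits a machine-readable report with a
pass/fail verdict.  Failures at any stage abort with the stage name — an
audit never silently guesses past a broken input.

Conventions fixed here (and recorded in every report):

* the measured distribution is the gamma *reference* (the points scored),
  the planned one the *evaluated* distribution that is searched;
* the dose threshold applies to the measured dose, as a percentage of the
  same denominator as the dose criterion;
* Delta4 gamma is computed per plane against the matching planned plane and
  the passing rate pooled over all evaluated diodes of both planes;
* warnings (plan-constraint deviations, calibration plausibility, dpi
  mismatches, clipped pixels) never alter the verdict.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
import numpy as np

from . import __version__
from .arrays import (
    arccheck_geometry,
    arccheck_plan_plane,
    delta4_geometry,
    delta4_planes,
    read_measured_text,
    unwrap_arccheck,
)
from .dose_model import DoseGrid2D, PlanInfo, extract_plane, read_rt_dose, read_rt_plan
from .errors import VauditError
from .film import (
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
from .gamma import GammaCriteria, GammaResult, gamma_map, get_preset, passing_rate_verdict

__all__ = [
    "AuditConfig",
    "AuditReport",
    "AuditStageError",
    "film_audit",
    "array_audit",
    "check_plan_constraints",
    "render_report",
]

EXPECTED_FRACTIONS = 10
EXPECTED_PRESCRIPTION_GY = 20.0
#: relative deviation of film vs planned dose in the high-dose region above
#: which the calibration is flagged suspect
CALIBRATION_SUSPECT_TOL = 0.05


class AuditStageError(VauditError):
    """A pipeline stage failed; carries the stage name and the input."""

    def __init__(self, stage: str, cause: Exception, detail: str = ""):
        self.stage = stage
        self.cause = cause
        super().__init__(f"audit aborted at stage '{stage}': {cause}" + (f" ({detail})" if detail else ""))

    def report_fragment(self) -> dict:
        return {"aborted_at_stage": self.stage, "error": str(self.cause)}


@dataclass
class AuditConfig:
    """Knobs of one audit run; everything has a credentialing default."""

    preset: str | GammaCriteria = "jcog-film"
    film_orientation: str = "axial"  # plane the film was placed in (declared, not detected)
    expected_dpi: float = 150.0
    layout_path: str | None = None
    subfilm_margin_fraction: float = 0.2
    arccheck_radius_mm: float | None = None  # override the vendor-default radius
    plan_plane_spacing_mm: float = 1.0

    def criteria(self) -> GammaCriteria:
        return self.preset if isinstance(self.preset, GammaCriteria) else get_preset(self.preset)


@dataclass
class AuditReport:
    """Machine-readable outcome of one credentialing audit."""

    device: str
    inputs: dict[str, str]  # path -> sha256
    criteria: dict
    denominator_gy: float
    n_reference: int
    n_evaluated: int
    passing_rate: float  # percent
    verdict: str  # "pass" | "fail"
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AuditReport":
        return cls(**d)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance() -> dict:
    return {
        "software": "vaudit",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
    }


def _stage(name: str):
    """Decorator-free stage wrapper: run ``fn`` and re-raise under the stage name."""

    class _Ctx:
        def __init__(self, stage):
            self.stage = stage

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, AuditStageError):
                raise AuditStageError(self.stage, exc) from exc
            return False

    return _Ctx(name)


def check_plan_constraints(plan: PlanInfo) -> list[str]:
    """Warn when the submitted plan deviates from the audit prescription.

    The audit plan prescribes 20 Gy in 10 fractions to the C-shaped target;
    coverage and organ-at-risk limits would need the structure set, which is
    out of scope, so only fractionation and prescription are checked here.
    """
    warnings = []
    if plan.n_fractions is None:
        warnings.append("plan fractionation absent: 10-fraction scheme not verifiable")
    elif plan.n_fractions != EXPECTED_FRACTIONS:
        warnings.append(
            f"plan has {plan.n_fractions} fractions, audit protocol expects {EXPECTED_FRACTIONS}"
        )
    if plan.prescription_dose is None:
        warnings.append("prescription dose absent: 20 Gy prescription not verifiable")
    elif abs(plan.prescription_dose - EXPECTED_PRESCRIPTION_GY) > 1e-6:
        warnings.append(
            f"prescription {plan.prescription_dose:g} Gy differs from the expected "
            f"{EXPECTED_PRESCRIPTION_GY:g} Gy (coverage/OAR checks need structures; not performed)"
        )
    return warnings


def _build_report(device, inputs, criteria, result: GammaResult, warnings) -> AuditReport:
    verdict = passing_rate_verdict(result)
    crit_dict = result.to_dict()["criteria"]
    return AuditReport(
        device=device,
        inputs={str(p): _checksum(p) for p in inputs},
        criteria=crit_dict,
        denominator_gy=float(result.denominator),
        n_reference=int(result.n_reference),
        n_evaluated=int(result.n_evaluated),
        passing_rate=float(result.passing_rate),
        verdict=verdict,
        warnings=list(warnings),
        provenance=_provenance(),
    )


# ---------------------------------------------------------------------------
# film workflow
# ---------------------------------------------------------------------------


def film_audit(
    scan_path,
    rt_dose_path,
    rt_plan_path,
    config: AuditConfig | None = None,
    unset_scan_path=None,
    layout: ScanLayout | None = None,
) -> AuditReport:
    """Run the full film credentialing workflow and return the report.

    Stages: read plan/dose, read scan, red channel, optical density, unset
    correction, subfilm calibration, dose conversion, fiducial registration,
    plan plane extraction, gamma analysis, verdict.
    """
    config = config or AuditConfig(preset="jcog-film")
    criteria = config.criteria()
    warnings: list[str] = []

    with _stage("dose_model"):
        plan_grid = read_rt_dose(rt_dose_path)
        plan_info = read_rt_plan(rt_plan_path)
    warnings += check_plan_constraints(plan_info)

    with _stage("film.read_scan"):
        scan = read_scan(scan_path, expected_dpi=config.expected_dpi)
        warnings += scan.warnings
        if layout is None:
            if config.layout_path is None:
                raise VauditError("no scan layout provided (config.layout_path or layout=)")
            layout = ScanLayout.load(config.layout_path)
        layout.validate(scan.pixels.shape)

    with _stage("film.optical_density"):
        od = optical_density(red_channel(scan))

    with _stage("film.correct_nonuniformity"):
        if unset_scan_path is not None:
            from scipy.ndimage import median_filter

            unset_scan = read_scan(unset_scan_path, expected_dpi=config.expected_dpi)
            warnings += [f"unset scan: {w}" for w in unset_scan.warnings]
            unset_od = optical_density(red_channel(unset_scan))
            if unset_od.shape != od.shape:
                raise VauditError(
                    f"unset scan shape {unset_od.shape} != film scan shape {od.shape}"
                )
            # smooth only the correction map, never the data
            unset_ref = median_filter(unset_od, size=5)
            warnings.append("non-uniformity correction: 2-D unset-film map")
        else:
            zero_rects = [r for r, d in layout.subfilms if d == 0]
            unset_ref = mean_region_od(od, zero_rects[0], config.subfilm_margin_fraction)
            warnings.append(
                "non-uniformity correction: scalar baseline from the 0 Gy subfilm "
                "(no unset-film scan supplied)"
            )
        net_od, n_clipped = correct_nonuniformity(od, unset_ref)
        if n_clipped:
            warnings.append(f"net OD: {n_clipped} sub-base pixels clipped to 0")

    with _stage("film.fit_calibration"):
        points = [
            (mean_region_od(net_od, rect, config.subfilm_margin_fraction), dose)
            for rect, dose in layout.subfilms
        ]
        curve = fit_calibration(points)

    with _stage("film.apply_calibration"):
        film_net_od = net_od[layout.film.slices]
        dose_film, cal_warnings = apply_calibration(curve, film_net_od, scan.dpi)
        warnings += cal_warnings

    with _stage("film.detect_fiducials"):
        fid = detect_fiducials(film_net_od)

    with _stage("film.align_to_isocenter"):
        measured = align_to_isocenter(dose_film, fid)

    with _stage("dose_model.extract_plane"):
        iso = plan_info.isocenter
        coord = {"axial": iso[2], "coronal": iso[1], "sagittal": iso[0]}[config.film_orientation]
        planned = extract_plane(plan_grid, config.film_orientation, coord)
        iso_uv = {
            "axial": (iso[0], iso[1]),
            "coronal": (iso[0], iso[2]),
            "sagittal": (iso[1], iso[2]),
        }[config.film_orientation]
        planned = planned.recentered(*iso_uv)

    warnings += _calibration_plausibility(measured, planned)

    with _stage("gamma"):
        result = gamma_map(measured, planned, criteria)

    inputs = [scan_path, rt_dose_path, rt_plan_path] + (
        [unset_scan_path] if unset_scan_path else []
    )
    report = _build_report("film", inputs, criteria, result, warnings)
    report.provenance["film_dpi"] = scan.dpi
    report.provenance["film_rotation_deg"] = round(fid.rotation_deg, 3)
    report.provenance["calibration_coeffs"] = [round(float(c), 6) for c in curve.coeffs]
    return report


def _calibration_plausibility(measured: DoseGrid2D, planned: DoseGrid2D) -> list[str]:
    """Compare film and planned dose levels on the high-dose plateau.

    A miscalibrated subfilm (e.g. the 2 Gy patch actually exposed above
    2 Gy) rescales the whole converted film; the mean measured/planned dose
    ratio over the planned >=90%-of-max region exposes that even when the
    gamma rate alone would not name the cause.
    """
    interp_pos, measured_dose = measured.points()
    if measured_dose.size == 0:
        return []
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (planned.v, planned.u), planned.values, bounds_error=False, fill_value=np.nan
    )
    planned_at = interp(interp_pos[:, ::-1])
    peak = float(np.nanmax(planned.values))
    sel = np.isfinite(planned_at) & (planned_at >= 0.9 * peak)
    if not np.any(sel):
        return []
    ratio = float(np.mean(measured_dose[sel]) / np.mean(planned_at[sel]))
    if abs(ratio - 1.0) > CALIBRATION_SUSPECT_TOL:
        return [
            f"calibration-suspect: film/planned dose ratio {ratio:.3f} in the high-dose "
            f"region (tolerance +/-{CALIBRATION_SUSPECT_TOL:.0%}); check subfilm doses"
        ]
    return []


# ---------------------------------------------------------------------------
# array workflow
# ---------------------------------------------------------------------------


def array_audit(
    measured_path,
    rt_dose_path,
    rt_plan_path,
    device: str,
    config: AuditConfig | None = None,
) -> AuditReport:
    """Run the array-detector credentialing workflow and return the report.

    ArcCHECK: measured diodes and the planned dose are both mapped onto the
    unwrapped cylinder surface.  Delta4: gamma per orthogonal plane at the
    isocenter, passing rate pooled over all evaluated diodes.
    """
    config = config or AuditConfig(preset="jcog-array")
    criteria = config.criteria()
    warnings: list[str] = []

    with _stage("dose_model"):
        plan_grid = read_rt_dose(rt_dose_path)
        plan_info = read_rt_plan(rt_plan_path)
    warnings += check_plan_constraints(plan_info)
    iso = np.asarray(plan_info.isocenter, float)

    with _stage("arrays.geometry"):
        if device == "arccheck":
            radius = config.arccheck_radius_mm
            geom = arccheck_geometry(radius_mm=radius) if radius else arccheck_geometry()
        elif device == "delta4":
            geom = delta4_geometry()
        else:
            raise VauditError(f"unknown device {device!r}")

    with _stage("arrays.read_measured_text"):
        measured = read_measured_text(measured_path, device, geometry=geom)

    if device == "arccheck":
        with _stage("arrays.unwrap"):
            ref_pos, ref_dose = unwrap_arccheck(measured, geom)
            planned = arccheck_plan_plane(
                plan_grid, geom, spacing_mm=config.plan_plane_spacing_mm, center=iso
            )
        with _stage("gamma"):
            result = gamma_map((ref_pos, ref_dose), planned, criteria)
    else:
        with _stage("arrays.planes"):
            planes = delta4_planes(measured, geom)
            planned_planes = {}
            for name in ("coronal", "sagittal"):
                coord = iso[1] if name == "coronal" else iso[0]
                iso_uv = (iso[0], iso[2]) if name == "coronal" else (iso[1], iso[2])
                planned_planes[name] = extract_plane(plan_grid, name, coord).recentered(*iso_uv)
        with _stage("gamma"):
            # one denominator per dataset: the maximum calculated dose over both planes
            from .gamma import resolve_denominator

            if criteria.denominator_mode == "max_of_evaluated":
                denom = max(
                    resolve_denominator(criteria, planned_planes["coronal"]),
                    resolve_denominator(criteria, planned_planes["sagittal"]),
                )
                pooled_criteria = dataclasses.replace(
                    criteria, denominator_mode="fixed_dose", denominator_dose=denom
                )
            else:
                pooled_criteria = criteria
            per_plane = [
                gamma_map(planes[name], planned_planes[name], pooled_criteria)
                for name in ("coronal", "sagittal")
            ]
            gammas = np.concatenate([r.gamma for r in per_plane])
            n_eval = sum(r.n_evaluated for r in per_plane)
            n_pass = sum(
                int(np.count_nonzero(r.gamma[np.isfinite(r.gamma)] <= 1.0)) for r in per_plane
            )
            result = GammaResult(
                gamma=gammas,
                n_evaluated=n_eval,
                passing_rate=100.0 * n_pass / n_eval,
                criteria=pooled_criteria,
                denominator=per_plane[0].denominator,
                n_reference=sum(r.n_reference for r in per_plane),
            )

    report = _build_report(device, [measured_path, rt_dose_path, rt_plan_path], criteria, result, warnings)
    if device == "arccheck":
        report.provenance["arccheck_radius_mm"] = geom.radius_mm
        report.provenance["arccheck_n_detectors"] = geom.n_detectors
    return report


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_report(report: AuditReport, fmt: str = "json") -> str:
    """Serialize a report: lossless JSON, or a human-readable text summary."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=1)
    if fmt != "text":
        raise VauditError(f"unknown report format {fmt!r}")
    c = report.criteria
    lines = [
        f"vaudit credentialing report ({report.device})",
        f"criteria: {c['dose_tolerance_percent']:g}%/{c['dta_mm']:g} mm global, "
        f"threshold {c['threshold_percent']:g}%, tolerance {c['pass_tolerance_percent']:g}%",
        f"dose denominator: {report.denominator_gy:.4g} Gy ({c['denominator_mode']})",
        f"evaluated points: {report.n_evaluated} of {report.n_reference}",
        f"gamma passing rate: {report.passing_rate:.1f}%",
        f"verdict: {report.verdict.upper()}",
    ]
    for path, digest in report.inputs.items():
        lines.append(f"input: {path} sha256={digest[:12]}...")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"
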