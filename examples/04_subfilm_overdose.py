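"""The failure mode film audits exist to catch: a miscalibrated subfilm.

If the calibration patch labelled 2 Gy was actually exposed to 2.293 Gy,
the fitted curve under-reads every film dose by ~13%.  A postal audit
that re-tunes a reference curve to the subfilms cannot see this; scoring
the curve fitted *only* from the submitted subfilms, as done here, drives
the gamma passing rate far below the 90% tolerance and flags the
calibration as suspect.  (Takes ~1 minute: the gamma search works hard
when distributions genuinely disagree.)
"""

import tempfile

from vaudit import AuditConfig, extract_plane, film_audit
from vaudit.synth import Scenario, make_c_shape_dose, make_film_scan, write_rt_files

with tempfile.TemporaryDirectory() as tmp:
    grid, plan_info = make_c_shape_dose(Scenario(seed=1))
    dose_path, plan_path = write_rt_files(grid, plan_info, tmp, seed=1)
    plane = extract_plane(grid, "axial", 0.0).recentered(0.0, 0.0)

    for label, scenario in (
        ("correct subfilms ", Scenario(seed=1)),
        ("2 Gy patch at 2.293", Scenario(seed=1, subfilm_actual_gy=2.293)),
    ):
        tiff, layout, unset = make_film_scan(plane, scenario, tmp + "/" + label.strip())
        report = film_audit(
            tiff, dose_path, plan_path,
            config=AuditConfig(preset="jcog-film", layout_path=layout),
            unset_scan_path=unset,
        )
        flag = next((w for w in report.warnings if "calibration-suspect" in w), "")
        print(f"{label}: {report.passing_rate:5.1f}% -> {report.verdict}  {flag}")
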