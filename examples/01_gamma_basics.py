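"""Gamma-index basics: closed forms you can verify by hand.

Builds two spatially uniform dose planes and scores one against the other
with the film credentialing preset (3%/3 mm global, denominator 2 Gy).
For uniform fields the distance term can never compensate a dose offset,
so gamma is exactly |dose difference| / (3% of 2 Gy) at every point.
"""

import numpy as np

from vaudit import DoseGrid2D, PRESETS, gamma_map, passing_rate_verdict

planned = DoseGrid2D(np.full((21, 21), 2.00), origin=(0, 0), spacing=(1.0, 1.0))

for measured_dose in (2.00, 2.05, 2.08):
    measured = DoseGrid2D(np.full((21, 21), measured_dose), origin=(0, 0), spacing=(1.0, 1.0))
    result = gamma_map(measured, planned, PRESETS["jcog-film"])
    gamma = np.nanmax(result.gamma)
    print(
        f"measured {measured_dose:.2f} Gy vs planned 2.00 Gy: "
        f"gamma = {gamma:.4f}, passing rate {result.passing_rate:.1f}%, "
        f"verdict {passing_rate_verdict(result)}"
    )

print()
print("gamma <= 1 means a point agrees within 3% dose or 3 mm distance;")
print("0.05/0.06 Gy offsets bracket the tolerance: 0.833 passes, 1.333 fails.")
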