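# vaudit — virtual-audit toolkit for IMRT dosimetry credentialing

Institutions joining clinical trials that use intensity-modulated radiation
therapy (IMRT) must first demonstrate that what their machine delivers
matches what their planning system calculates.  In a *virtual* audit the
institution irradiates its own dosimeter — radiochromic film or a
commercial diode array (ArcCHECK, Delta4) — on a common C-shaped target
plan and uploads the raw measurement plus the planned dose (DICOM-RT);
the auditing group's software performs the whole analysis independently.
`vaudit` implements that analysis end to end for medical physicists and
trial QA groups:

* a **film pipeline**: composite 150 dpi 48-bit scan → red channel → net
  optical density (unset-film non-uniformity correction) → subfilm
  calibration (origin-constrained polynomial, degree ≤ 3) → fiducial
  registration to the isocenter → absolute 2-D dose;
* an **array pipeline**: measured text exports mapped onto the device
  geometry — the ArcCHECK helix unwrapped onto its cylinder surface, the
  Delta4 boards as coronal/sagittal planes — with the planned dose sampled
  at the same coordinates;
* a **global gamma-index engine** with credentialing presets and a
  brute-force oracle;
* a **seeded synthetic-data generator** producing every input (C-shaped
  plan as RT Dose/Plan, film TIFF + layout, measured text) with optional
  planted delivery errors, so the whole system is testable without any
  institutional data.

## The statistic at the core

Each measured point `r` with dose `Dm(r)` is scored against the planned
distribution `Dp`:

    γ(r) = min over positions e of sqrt( |e − r|² / Δd²  +  (Dp(e) − Dm(r))² / ΔD² )

with distance-to-agreement `Δd` and absolute dose tolerance
`ΔD = δ·D_norm/100` (global gamma: one denominator `D_norm` for the whole
dataset).  A point passes when γ ≤ 1; the **passing rate** over points
above the dose threshold decides the audit:

| preset       | criteria  | denominator            | threshold | tolerance |
|--------------|-----------|------------------------|-----------|-----------|
| `jcog-film`  | 3% / 3 mm | fixed 2 Gy             | 30%       | 90%       |
| `jcog-array` | 3% / 2 mm | max calculated dose    | 10%       | 95%       |

No dataset is ever rescaled: film and detectors are converted to absolute
Gy for the single delivered fraction and compared as-is.

## Worked example

`examples/` contains one short script per capability.  The closed form
every gamma implementation should reproduce (`examples/01_gamma_basics.py`):

```
measured 2.00 Gy vs planned 2.00 Gy: gamma = 0.0000, passing rate 100.0%, verdict pass
measured 2.05 Gy vs planned 2.00 Gy: gamma = 0.8333, passing rate 100.0%, verdict pass
measured 2.08 Gy vs planned 2.00 Gy: gamma = 1.3333, passing rate 0.0%, verdict fail
```

For uniform fields the distance term cannot help, so γ is exactly
|ΔD|/(3% · 2 Gy): a 0.05 Gy offset passes (0.833), 0.08 Gy fails (1.333).

A full film audit on a synthetic submission (`examples/02_film_audit.py`):

```
vaudit credentialing report (film)
criteria: 3%/3 mm global, threshold 30%, tolerance 90%
dose denominator: 2 Gy (fixed_dose)
evaluated points: 320014 of 348100
gamma passing rate: 99.9%
verdict: PASS
```

and the failure mode film audits exist to catch
(`examples/04_subfilm_overdose.py`) — a calibration subfilm labelled 2 Gy
but actually exposed to 2.293 Gy:

```
correct subfilms   :  99.9% -> pass
2 Gy patch at 2.293:  79.3% -> fail  calibration-suspect: film/planned dose
                                     ratio 0.884 in the high-dose region
```

Array audits (`examples/03_array_audit.py`) pass a correct delivery at
100.0% on both devices and fail a +5% machine-output error (ArcCHECK
40.7%, Delta4 84.9%, both far below the 95% tolerance).

## Command line

```
vaudit synth --seed 1 --out DATA                       # generate a submission
vaudit film  --scan DATA/scan.tif --unset DATA/unset.tif \
             --dose DATA/rtdose.dcm --plan DATA/rtplan.dcm \
             --layout DATA/layout.json -o report.json
vaudit array --device arccheck --measured DATA/measured_arccheck.txt \
             --dose DATA/rtdose.dcm --plan DATA/rtplan.dcm -o report.json
```

Exit codes: 0 = pass, 1 = fail, 2 = error.

## Scope

`vaudit` analyses submissions; it does not plan treatments, compute DVHs,
model beams, or talk to a server.  Planar array detectors, oblique dose
grids and vendor-native binary export formats are out of scope; the
measured-text dialect it reads is its own documented format
(see `docs/methods.md`).
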