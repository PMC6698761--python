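# planlint

Automated, vendor-independent quality checks for external-beam radiotherapy
treatment plans.

Most treatment-delivery errors originate in treatment planning, and the
physics plan check is the single most effective step for catching them — but
a manual check is slow and misses a large share of catchable defects. This
package re-implements the core of a rule-based **automated plan check**: it
reads a DICOM RT Plan / RT Structure Set (and optionally RT Dose) file set,
compares it against a *prescription directive* (a small YAML/JSON sidecar
carrying what the record-and-verify system holds: site, laterality,
fractionation, energy, bolus intent, special-consideration flags, OAR dose
limits), and emits a color-coded PASS / WARN / FAIL report with a reason for
every non-pass. It also generates and verifies therapist **shift
instructions** (user origin → isocenter, mapped into couch axes per patient
position), the single highest-risk failure mode in plan checking.

Around the check engine sit the quality-management tools that decide *which*
checks matter and measure whether automation helped:

- **FMEA** (`planlint.fmea`) — risk priority numbers `RPN = S·O·D` on the
  TG-100 1–10 scales, Pareto ranking, automation-candidate selection
  (high RPN ∪ severity > 7), and paired t-test comparison of pre/post
  re-scoring phases.
- **Six Sigma** (`planlint.sixsigma`) — defects per opportunity
  `DPO = errors / (opportunities_per_plan × n_plans)`, the sigma level
  `Φ⁻¹(1 − DPO) + 1.5` under the conventional 1.5σ long-term shift, integer
  sigma class (floor), and process yield.
- **Synthetic data** (`planlint.synthetic_data`) — a deterministic generator
  of geometrically valid DICOM plan sets that are clean by construction,
  plus a 13-entry catalogue of injectable defects (wrong dose/fraction,
  wrong energy, missing bolus, flipped shift sign, unset user origin, …),
  each mapped to the one check that must flag it. This is how the engine's
  sensitivity (no false negatives) and specificity (no false positives) are
  validated.
- **Audit reporting** (`planlint.audit_reporting`) — an append-only
  JSON-lines store of every check run and first-vs-final-run error-rate
  statistics, the direct evidence that flagged errors get fixed before plan
  approval.

## Worked example

Generate a synthetic plan set and check it:

```
$ planlint generate --seed 42 --out plan42
wrote plan42 (plan Pelvis_HFS_0042)
$ planlint check --rtplan plan42/rtplan.dcm --rtstruct plan42/rtstruct.dcm \
    --rtdose plan42/rtdose.dcm --rx plan42/directive.yaml
Plan check report — Pelvis_HFS_0042 (config b2a183fb8938432a)
  [PASS ] rx_site_laterality: site and laterality consistent
  [PASS ] orientation_consistency: image orientation matches patient position
  [PASS ] rx_fractionation: fractionation matches prescription
  [PASS ] flag_cardiac_device: no cardiac device flag
  [PASS ] flag_previous_rt: no previous RT flag
  [PASS ] user_origin: user origin set and inside BODY
  [PASS ] mu_sanity: MU/cGy ratio 2.57 plausible
  [PASS ] shift_note: shift note verified
  [PASS ] clearance: max body extent 132 mm within clearance proxy radius 400 mm
  [PASS ] dose_limits: OAR_Sphere: MAX dose 1800.0 cGy within limit 3000.0 cGy
  [PASS ] rx_energy_bolus: energy and bolus match prescription
  11 pass / 0 warn / 0 fail / 0 n/a
```

Every check passes because the generator is clean by construction; inject a
defect (`planlint.synthetic_data.inject_error`) and exactly the designated
check flips. The shift note for the same plan:

```
$ planlint shiftnote --rtplan plan42/rtplan.dcm --rtstruct plan42/rtstruct.dcm
LAT: -1.4 cm RIGHT
VERT: -0.7 cm POST
LONG: +2.9 cm SUP
```

reads: move the couch 1.4 cm so the patient shifts toward their right,
0.7 cm posterior, 2.9 cm superior — signed values are couch axes, direction
words are patient anatomy. Six Sigma arithmetic on an observed error count
(13 errors over 1000 plans at 5 opportunities each):

```
$ planlint sixsigma --errors 13 --opps 5 --plans 1000
DPO         = 2.600e-03
sigma level = 4.29 (class 4)
yield       = 99.740%
```

i.e. a 4σ process: each of the 5000 opportunities had a 0.26% chance of a
defect. Simulate check–fix–recheck QA cycles and summarize the audit trail:

```
$ planlint simulate --n 8 --fix-prob 1.0 --seed 3 --out audit.jsonl
$ planlint audit summary audit.jsonl
first-run error rate: 2/88 = 0.023
final-run error rate: 0/88 = 0.000
```

With a fix probability of 1 every caught defect is corrected, so the final
run is clean — the drop from first to final run is the simulator's measure
of errors stopped before approval.

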