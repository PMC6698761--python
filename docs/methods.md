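# Methods

This note records the conventions, parameter choices and limitations behind
`planlint` — what the checks actually compute, what the synthetic data
emulates, and where the design was genuinely open.

## Plan model and units

Everything internal is DICOM patient LPS coordinates in millimetres
(+x patient left, +y posterior, +z superior) and centigray; shift notes
render centimetres to one decimal, the clinical display convention. The
loader normalizes an RT Plan / RT Structure Set / RT Dose triple into one
`TreatmentPlan`:

- fraction count from `NumberOfFractionsPlanned`; total dose from
  `TargetPrescriptionDose`; dose per fraction as the sum of per-beam
  `BeamDose` contributions. These are three *independent* DICOM attributes,
  so plan-internal inconsistency is possible and is deliberately **not** a
  load error: it surfaces through the prescription-match check instead. A
  hard load gate would hide exactly the defects a checker exists to catch.
  (The directive side *is* hard-validated: an internally inconsistent
  prescription cannot anchor any check.)
- the user origin is read from a POINT-contour `MARKER` ROI named
  `UserOrigin` in the structure set — vendor systems store this reference
  point internally, so a file-level dialect had to be defined. Absent
  marker ⇒ `user_origin_set = False`.
- the CT's direction cosines are taken from the RT Dose
  `ImageOrientationPatient` when a dose file is present (no CT file is in
  scope), else from the structure set, else the canonical cosines for the
  stated position.
- multi-isocenter and decubitus plans are rejected at load: the check
  semantics (single shift note, laterality from one isocenter) do not cover
  them, and failing loudly beats half-checking.
- dose lookup is nearest-voxel / nearest-slice with per-slice
  point-in-polygon membership at voxel centers — no trilinear
  interpolation. Simplest defensible rule; limits can be tightened later
  without changing the interface.

## Check registry

Statuses: objective mismatches (prescription vs plan, orientation, user
origin, shift note, OAR limit) are FAIL; judgment items the software cannot
adjudicate (special-consideration flags, MU ratio, clearance) are WARN;
rules whose operands are absent return NOT_APPLICABLE and are excluded from
error-rate denominators. Severity seeds use the published committee scores
for the named high-severity items; checks without a published score default
to 5.

Default tolerances (registry parameters, not claims about any clinic):

| parameter | default | rationale |
|---|---|---|
| fractionation dose tolerance | 0.5 cGy | sub-rounding-unit agreement |
| laterality offset tolerance | 20 mm | generous mid-sagittal band; a true wrong-side plan is decimetres off |
| MU/cGy plausibility band | 0.8–5.0, inclusive | spans conventional 3D/IMRT modulation; a factor-10 scale error lands far outside |
| clearance proxy radius | 400 mm | typical bore/gantry clearance radius |
| shift-note verify tolerance | 0.05 cm | half of the 0.1 cm display resolution |
| orientation cosine tolerance | 1e-3 per component | numerically exact for real headers |

Site matching is token containment after case-folding and stripping
non-alphanumerics; no richer string rule is defensible without
institution-specific data. The clearance check is a documented *proxy* —
maximum body-contour distance from the isocenter perpendicular to each beam
axis on the isocenter slice — not machine-geometry collision modelling.

## Shift instructions

The displacement is isocenter − user origin in patient coordinates; its
anatomical reading (LEFT/RIGHT, ANT/POST, SUP/INF) is position-invariant.
Room axes are ordered (LAT, LONG, VERT); each patient position maps patient
axes to room axes by a proper rotation (determinant +1, verified by
property test and by an independent axis-angle oracle built with scipy):
head-first supine is the base, feet-first composes a half-turn about the
room vertical axis, prone a half-turn about the room longitudinal axis.
Magnitudes are rounded to 0.1 cm *half away from zero* — the tie at 0.05 cm
rounds outward, which matters because the verify tolerance equals 0.05 cm.
The note grammar is versioned and fixed: one line per couch axis,
`<AXIS>: <±d.d> cm <DIRECTION>`, or the exact sentence
`No shifts — treat at marked origin`. Couch-top (table-top) content is a
free-text pass-through, not computed.

## FMEA and Six Sigma

RPN = S·O·D with each factor validated to [1, 10]; fractional scores are
allowed because committee averages are fractional. Pareto ranking breaks
RPN ties by severity, then item name (stable, permutation-invariant).
Automation candidates are the union of {RPN ≥ cutoff} and
{severity strictly > 7}: the strict inequality keeps a severity-7.0 item
out, and the union keeps rare-but-catastrophic items in.

The phase comparison pairs items by name and computes the two-sided paired
t-test directly from the mean and SD of per-item RPN differences (scipy's
`ttest_rel` serves as an independent cross-check in the tests, never as the
implementation). Zero-variance differences make the statistic undefined;
we return `p = NaN` with a `degenerate` flag rather than a fake 0.

Sigma arithmetic uses the 1.5σ long-term-shift convention —
`sigma_level = Φ⁻¹(1 − DPO) + 1.5` — the only convention consistent with
the standard pairings 6σ ↔ 3.4 × 10⁻⁶ DPO and 5σ ↔ 99.977% yield. The
integer sigma *class* is the floor of the level: a process at level 4.64
has not reached 5σ. Occurrence scores from incident-report counts use a
log10-frequency table (each decade of per-plan rate spans ≈ 3 score
points); the mapping is a documented package choice.

## Synthetic data

The generator emulates the record-and-verify + planning-system data a
checker sees, not anatomy: the body is an elliptic cylinder (~30 × 20 cm
cross-section, 20 cm long, 1 cm slices), the target and one OAR are
spheres, and the dose grid (8 × 8 × 10 mm) is painted uniform-prescription
inside the target and uniform 30% of prescription elsewhere inside the
body. Analytic geometry gives every check a closed-form expected value —
the OAR's dose is *exactly* the background level because the OAR is placed
≥ 70 mm from the isocenter, outside the target sphere by construction.
Defaults describe a conventionally fractionated photon plan: 2 Gy × 30,
6 MV, two beams, MU/cGy drawn from [1, 3], isocenter offset 5–30 mm per
axis from the marked origin (lower-bounded at 5 mm so every shift-note axis
has an unambiguous direction word). A fixed seed yields byte-identical
files (fixed dates; UIDs derived deterministically from the seed).

The 13-entry error catalogue mutates exactly one attribute per entry, each
mapped to the one check that must flag it. One documented coupling exists:
removing the user origin necessarily also turns the shift-note check
NOT_APPLICABLE (the truth it verifies against cannot be computed); the
minimality test permits exactly that transition and nothing else.

`simulate_qa_runs` models the check–fix–recheck cycle: per plan, each
catalogue error is injected independently with its mix probability; caught
errors (designated check FAILed/WARNed) are fixed with probability
`fix_prob`; first and final runs are recorded to the audit store. Child
seeds derive from the master seed by counter, so cohorts are reproducible.
Because real per-category error base rates are not publishable knowledge,
the default mix is illustrative only.

What passing these tests shows — and does not show: 100% sensitivity and 0
false positives hold *for this catalogue on this phantom at the default
tolerances*. Real plans have multi-target prescriptions, irregular
contours, setup-field conventions and vendor dialect quirks the phantom
does not model; the suite validates the rule logic and plumbing, not
clinical completeness.

## Error-rate statistics

The audit store is an append-only JSON-lines file; `(plan_id, run_index)`
is unique and run indices increment per plan. The error rate is
(FAIL + WARN) / (all results except NOT_APPLICABLE), reported as an exact
rational. WARN counts as a defect by default because a WARN demands
reviewer attention; `count_warn=False` restricts to hard FAILs, and the
choice is explicit in every API. Problem sizes in the shipped tests —
20 seeds per error type, 50 clean plans, cohorts of ≈ 10–60 simulated
plans, 1000 oracle displacements per position — were chosen as the smallest
sizes at which the binomial and property bounds being asserted are sharp.

## Known limitations

- Single fraction group, single isocenter, photon/electron labels of the
  form `6X`/`6E`; no wedges, no VMAT control-point modelling (MU sanity is
  a ratio test, not a dose recalculation).
- The clearance proxy ignores couch kick angles and gantry head geometry.
- Dose statistics are voxel-center counting; small structures relative to
  the grid spacing will be noisy (the tests use structures ≥ 2 voxels
  across).
- The directive schema is an explicit stand-in for record-and-verify
  database access; field names do not claim fidelity to any vendor schema.
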