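"""Therapist shift instructions: user origin -> isocenter.

Incorrect shift instructions are the highest-risk failure mode an automated
plan checker addresses: a sign flip moves the patient the wrong way on the
couch.  This module computes the instruction from plan geometry and verifies
a free-text note against the computed truth.

Geometry
--------
The displacement is ``isocenter - user_origin`` in DICOM patient LPS
coordinates (mm).  Its anatomical reading is position-invariant, because
LPS axes are anchored to the patient: +x is a shift toward the patient's
LEFT, +y toward POSTerior, +z toward SUPerior.

Couch (room) axes depend on how the patient lies.  We order room axes as
(LAT, LONG, VERT); each patient position then maps patient axes to room
axes by a proper rotation (determinant +1):

=========  =========  ==========  ==========
position   LAT        LONG        VERT
=========  =========  ==========  ==========
HFS        +x (LEFT)  +z (SUP)    -y (ANT+)
HFP        -x         +z          +y
FFS        -x         -z          -y
FFP        +x         -z          +y
=========  =========  ==========  ==========

Magnitudes are displayed in cm, rounded to 0.1 cm half-away-from-zero (the
clinical display convention; ties at 0.05 cm round outward).

Note grammar (versioned, one line per couch axis)::

    LAT: +1.0 cm LEFT
    VERT: +2.0 cm ANT
    LONG: +3.0 cm SUP

or exactly ``No shifts — treat at marked origin`` for a zero shift.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .check_engine import CheckResult, CheckStatus
from .plan_model import PatientPosition, TreatmentPlan

__all__ = [
    "ShiftInstruction",
    "COUCH_ROTATIONS",
    "compute_shifts",
    "render_note",
    "verify_shift_note",
    "NO_SHIFT_TEXT",
]

NO_SHIFT_TEXT = "No shifts — treat at marked origin"

#: Rotation matrices taking patient LPS displacement to room (LAT, LONG, VERT).
COUCH_ROTATIONS: dict[PatientPosition, np.ndarray] = {
    PatientPosition.HFS: np.array([[1, 0, 0], [0, 0, 1], [0, -1, 0]], dtype=float),
    PatientPosition.HFP: np.array([[-1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=float),
    PatientPosition.FFS: np.array([[-1, 0, 0], [0, 0, -1], [0, -1, 0]], dtype=float),
    PatientPosition.FFP: np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
}

# anatomical direction labels for positive/negative patient-axis components
_ANAT_LABELS = (("LEFT", "RIGHT"), ("POST", "ANT"), ("SUP", "INF"))


def round_half_away(value_cm: float, decimals: int = 1) -> float:
    """Round half away from zero (so 0.05 cm -> 0.1 cm, -0.05 -> -0.1)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(value_cm) * factor + 0.5) / factor, value_cm)


@dataclass(frozen=True)
class ShiftInstruction:
    displacement: np.ndarray                 # (3,) mm, isocenter - user_origin
    anatomical: tuple[tuple[str, float], ...]  # ((label, cm), ...) per patient axis
    couch: tuple[float, float, float]        # signed cm on (LAT, LONG, VERT)
    patient_position: PatientPosition
    note_text: str

    @property
    def couch_lat(self) -> float:
        return self.couch[0]

    @property
    def couch_long(self) -> float:
        return self.couch[1]

    @property
    def couch_vert(self) -> float:
        return self.couch[2]


def compute_shifts(plan: TreatmentPlan) -> ShiftInstruction:
    """Compute the shift instruction for one plan.

    Refuses plans whose user origin was never set (still at the scanner
    default): the user-origin check must pass first, otherwise the
    instruction would be measured from a meaningless point.
    """
    if not plan.user_origin_set:
        raise ValueError(
            "user origin not set; run check_user_origin first — "
            "a shift from the scanner default is meaningless"
        )
    disp = np.asarray(plan.isocenter, dtype=float) - np.asarray(plan.user_origin, dtype=float)
    return _instruction_from_displacement(disp, plan.patient_position)


def _instruction_from_displacement(disp: np.ndarray,
                                   position: PatientPosition) -> ShiftInstruction:
    anatomical = []
    for axis, component in enumerate(disp):
        pos_label, neg_label = _ANAT_LABELS[axis]
        label = pos_label if component >= 0 else neg_label
        anatomical.append((label, round_half_away(abs(component) / 10.0)))

    couch_vec = COUCH_ROTATIONS[position] @ disp      # mm, (LAT, LONG, VERT)
    couch = tuple(round_half_away(v / 10.0) for v in couch_vec)

    note = render_note(couch, anatomical)
    return ShiftInstruction(
        displacement=disp,
        anatomical=tuple(anatomical),
        couch=couch,  # type: ignore[arg-type]
        patient_position=position,
        note_text=note,
    )


def render_note(couch: tuple[float, float, float],
                anatomical: tuple[tuple[str, float], ...]) -> str:
    """Render the versioned note text from couch values + anatomical labels."""
    if all(v == 0.0 for v in couch):
        return NO_SHIFT_TEXT
    lat, long_, vert = couch
    lines = [
        f"LAT: {lat:+.1f} cm {anatomical[0][0]}",
        f"VERT: {vert:+.1f} cm {anatomical[1][0]}",
        f"LONG: {long_:+.1f} cm {anatomical[2][0]}",
    ]
    return "\n".join(lines)


_LINE_RE = re.compile(
    r"^\s*(LAT|VERT|LONG)\s*:\s*([+-]?\d+(?:\.\d+)?)\s*cm\s+(LEFT|RIGHT|ANT|POST|SUP|INF)\s*$",
    re.IGNORECASE,
)

# which anatomical axis each couch-axis direction word belongs to
_WORD_AXIS = {"LEFT": 0, "RIGHT": 0, "POST": 1, "ANT": 1, "SUP": 2, "INF": 2}


def verify_shift_note(note_text: str, plan: TreatmentPlan,
                      tol_cm: float = 0.05) -> CheckResult:
    """Check a free-text shift note against the geometry-derived instruction.

    FAILs when any couch value differs from the computed one by more than
    ``tol_cm`` or any direction word is wrong; an unparseable note FAILs as
    malformed.  A zero-magnitude axis accepts either direction word.
    """
    expected = compute_shifts(plan)
    check_id = "shift_note"

    if note_text.strip() == NO_SHIFT_TEXT:
        if all(v == 0.0 for v in expected.couch):
            return CheckResult(check_id, CheckStatus.PASS, "shift note verified: no shifts")
        return CheckResult(
            check_id, CheckStatus.FAIL,
            f"note says no shifts but computed couch shifts are "
            f"LAT {expected.couch[0]:+.1f} / LONG {expected.couch[1]:+.1f} / "
            f"VERT {expected.couch[2]:+.1f} cm",
            observed=note_text, expected=expected.note_text)

    parsed: dict[str, tuple[float, str]] = {}
    for line in note_text.strip().splitlines():
        if not line.strip():
            continue
        m = _LINE_RE.match(line)
        if m is None:
            return CheckResult(check_id, CheckStatus.FAIL,
                               f"malformed note line: {line.strip()!r}",
                               observed=note_text, expected=expected.note_text)
        axis, value, word = m.group(1).upper(), float(m.group(2)), m.group(3).upper()
        parsed[axis] = (value, word)
    if set(parsed) != {"LAT", "VERT", "LONG"}:
        return CheckResult(check_id, CheckStatus.FAIL,
                           "malformed note: expected one line each for LAT, VERT, LONG",
                           observed=note_text, expected=expected.note_text)

    exp_by_axis = {"LAT": (expected.couch[0], expected.anatomical[0]),
                   "LONG": (expected.couch[1], expected.anatomical[2]),
                   "VERT": (expected.couch[2], expected.anatomical[1])}
    problems = []
    for axis in ("LAT", "VERT", "LONG"):
        value, word = parsed[axis]
        exp_value, (exp_word, exp_mag) = exp_by_axis[axis]
        if abs(value - exp_value) > tol_cm + 1e-12:
            problems.append(f"{axis} value {value:+.2f} cm, expected {exp_value:+.1f} cm")
        if exp_mag != 0.0 and word != exp_word:
            problems.append(f"{axis} direction {word}, expected {exp_word}")
        if _WORD_AXIS[word] != _WORD_AXIS[exp_word]:
            problems.append(f"{axis} direction word {word} belongs to the wrong axis")
    if problems:
        return CheckResult(check_id, CheckStatus.FAIL,
                           "shift note mismatch: " + "; ".join(problems),
                           observed=note_text, expected=expected.note_text)
    return CheckResult(check_id, CheckStatus.PASS, "shift note verified")
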