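"""Rule-based automated plan check engine.

Each check item is a predefined rule executed against a loaded
:class:`~planlint.plan_model.TreatmentPlan` and its
:class:`~planlint.plan_model.PrescriptionDirective`; the runner produces one
:class:`CheckResult` per enabled check and collects them into a
:class:`CheckReport` whose serialization is byte-stable for identical inputs.

Status semantics (our refinement of a two-level PASS/WARN display):

* ``FAIL`` — an objective mismatch between plan and prescription, geometry
  or safety rule (treat only after correction or explicit override).
* ``WARN`` — a judgment item the software cannot adjudicate (special-
  consideration flags, MU ratio, clearance proxy): the reviewer must look.
* ``NOT_APPLICABLE`` — the rule's operands are absent (e.g. no dose grid);
  retained in the report so error-rate denominators stay well-defined.

A check that raises internally is recorded as ``FAIL`` with an engine-error
message — never silently skipped.
"""

from __future__ import annotations

import fnmatch
import hashlib
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Callable, Optional

import numpy as np
from matplotlib.path import Path as MplPath

from .plan_model import (
    CANONICAL_ORIENTATIONS,
    Laterality,
    PrescriptionDirective,
    StructureRole,
    TreatmentPlan,
)

__all__ = [
    "CheckStatus",
    "CheckCategory",
    "CheckResult",
    "CheckItem",
    "CheckReport",
    "CheckRegistry",
    "default_registry",
    "run_checks",
    "check_rx_fractionation",
    "check_rx_energy_bolus",
    "check_rx_site_laterality",
    "check_orientation_consistency",
    "check_user_origin",
    "check_flags",
    "check_mu_sanity",
    "check_dose_limits",
    "check_clearance_proxy",
]


class CheckStatus(str, Enum):
    PASS = "PASS"
    WARN = "WARN"
    FAIL = "FAIL"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class CheckCategory(str, Enum):
    RX_MATCH = "RX_MATCH"
    GEOMETRY = "GEOMETRY"
    FLAGS = "FLAGS"
    DOSE = "DOSE"
    DELIVERY = "DELIVERY"


@dataclass(frozen=True)
class CheckResult:
    check_id: str
    status: CheckStatus
    message: str = ""
    observed: Optional[Any] = None
    expected: Optional[Any] = None

    def __post_init__(self):
        if self.status is not CheckStatus.PASS and not self.message:
            raise ValueError("non-PASS results must carry an explanatory message")

    def to_dict(self) -> dict:
        d = {"check_id": self.check_id, "status": self.status.value,
             "message": self.message}
        if self.observed is not None:
            d["observed"] = _jsonable(self.observed)
        if self.expected is not None:
            d["expected"] = _jsonable(self.expected)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CheckResult":
        return cls(check_id=d["check_id"], status=CheckStatus(d["status"]),
                   message=d.get("message", ""), observed=d.get("observed"),
                   expected=d.get("expected"))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return [x.item() for x in v]
    return v


@dataclass
class CheckItem:
    """One registry entry: a rule plus its severity seed and tolerances."""

    check_id: str
    category: CheckCategory
    severity: float
    func: Callable[[TreatmentPlan, PrescriptionDirective, dict], "CheckResult | list[CheckResult]"]
    enabled: bool = True
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (1.0 <= self.severity <= 10.0):
            raise ValueError("severity must lie in [1, 10]")


class CheckRegistry:
    """Ordered collection of check items (severity-descending by default)."""

    def __init__(self, items: list[CheckItem]):
        ids = [it.check_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate check_id in registry")
        self.items = sorted(items, key=lambda it: (-it.severity, it.check_id))

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def get(self, check_id: str) -> CheckItem:
        for it in self.items:
            if it.check_id == check_id:
                return it
        raise KeyError(check_id)

    def fingerprint(self) -> str:
        payload = [
            {"check_id": it.check_id, "category": it.category.value,
             "severity": it.severity, "enabled": it.enabled,
             "params": {k: it.params[k] for k in sorted(it.params)}}
            for it in self.items
        ]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class CheckReport:
    plan_id: str
    results: list[CheckResult]
    config_fingerprint: str
    run_timestamp: Optional[str] = None

    def by_id(self) -> dict[str, list[CheckResult]]:
        out: dict[str, list[CheckResult]] = {}
        for r in self.results:
            out.setdefault(r.check_id, []).append(r)
        return out

    def worst_status(self, check_id: str) -> CheckStatus:
        order = {CheckStatus.FAIL: 3, CheckStatus.WARN: 2,
                 CheckStatus.PASS: 1, CheckStatus.NOT_APPLICABLE: 0}
        results = self.by_id().get(check_id, [])
        if not results:
            raise KeyError(check_id)
        return max((r.status for r in results), key=order.get)

    def counts(self) -> dict[str, int]:
        c = {s.value: 0 for s in CheckStatus}
        for r in self.results:
            c[r.status.value] += 1
        return c

    def to_dict(self) -> dict:
        d = {
            "plan_id": self.plan_id,
            "config_fingerprint": self.config_fingerprint,
            "results": [r.to_dict() for r in self.results],
        }
        if self.run_timestamp is not None:
            d["run_timestamp"] = self.run_timestamp
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict) -> "CheckReport":
        return cls(plan_id=d["plan_id"],
                   results=[CheckResult.from_dict(r) for r in d["results"]],
                   config_fingerprint=d["config_fingerprint"],
                   run_timestamp=d.get("run_timestamp"))

    @classmethod
    def from_json(cls, s: str) -> "CheckReport":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Individual checks
# ---------------------------------------------------------------------------

def check_rx_fractionation(plan: TreatmentPlan, rx: PrescriptionDirective,
                           tol_frac_dose: float = 0.5) -> CheckResult:
    """Prescription vs plan: total dose, dose/fraction, fraction count.

    Fractions must agree exactly; doses within ``tol_frac_dose`` cGy.  The
    three sub-comparisons are reported in one result whose message names
    every mismatched quantity with both values.
    """
    problems = []
    if plan.fractions_planned != rx.fractions:
        problems.append(f"fractions: plan {plan.fractions_planned} vs rx {rx.fractions}")
    if abs(plan.dose_per_fraction - rx.dose_per_fraction) > tol_frac_dose:
        problems.append(
            f"dose per fraction: plan {plan.dose_per_fraction:g} vs rx "
            f"{rx.dose_per_fraction:g} cGy")
    if abs(plan.total_dose - rx.total_dose) > tol_frac_dose:
        problems.append(
            f"total dose: plan {plan.total_dose:g} vs rx {rx.total_dose:g} cGy")
    if problems:
        return CheckResult(
            "rx_fractionation", CheckStatus.FAIL, "; ".join(problems),
            observed=[plan.total_dose, plan.dose_per_fraction, plan.fractions_planned],
            expected=[rx.total_dose, rx.dose_per_fraction, rx.fractions])
    return CheckResult("rx_fractionation", CheckStatus.PASS,
                       "fractionation matches prescription")


def check_rx_energy_bolus(plan: TreatmentPlan, rx: PrescriptionDirective) -> CheckResult:
    """Beam energies within the prescribed set; bolus intent matches linkage."""
    problems = []
    for b in plan.treatment_beams():
        if b.energy not in rx.allowed_energies:
            problems.append(
                f"beam {b.beam_id}: energy {b.energy} not in prescribed "
                f"{sorted(rx.allowed_energies)}")
    any_bolus = any(b.bolus_linked for b in plan.treatment_beams())
    if rx.bolus_required and not any_bolus:
        problems.append("bolus prescribed but not linked to any treatment beam")
    if not rx.bolus_required and any_bolus:
        linked = [b.beam_id for b in plan.treatment_beams() if b.bolus_linked]
        problems.append(f"bolus linked on beam(s) {linked} but not prescribed")
    if problems:
        return CheckResult("rx_energy_bolus", CheckStatus.FAIL, "; ".join(problems))
    return CheckResult("rx_energy_bolus", CheckStatus.PASS,
                       "energy and bolus match prescription")


_NORM_RE = re.compile(r"[^a-z0-9]+")


def _normalize_label(text: str) -> str:
    return _NORM_RE.sub("", text.casefold())


def check_rx_site_laterality(plan: TreatmentPlan, rx: PrescriptionDirective,
                             lat_tol: float = 20.0) -> CheckResult:
    """Treatment site token in the plan label; laterality against geometry.

    Laterality is judged by the isocenter's lateral offset from the BODY
    centroid's mid-sagittal plane (+ toward patient left): LEFT/RIGHT plans
    must not sit more than ``lat_tol`` mm on the wrong side, MIDLINE plans
    must sit within ``lat_tol`` mm of the plane, NA skips the geometric test.
    """
    problems = []
    if _normalize_label(rx.site) not in _normalize_label(plan.plan_id):
        problems.append(f"plan label {plan.plan_id!r} does not mention site {rx.site!r}")

    body = plan.body()
    centroid_x = float(body.all_points()[:, 0].mean())
    offset = float(plan.isocenter[0]) - centroid_x    # + toward patient left
    side = "left" if offset >= 0 else "right"
    if rx.laterality is Laterality.LEFT and offset < -lat_tol:
        problems.append(
            f"rx laterality LEFT but isocenter {abs(offset):.0f} mm to patient-{side}")
    elif rx.laterality is Laterality.RIGHT and offset > lat_tol:
        problems.append(
            f"rx laterality RIGHT but isocenter {abs(offset):.0f} mm to patient-{side}")
    elif rx.laterality is Laterality.MIDLINE and abs(offset) > lat_tol:
        problems.append(
            f"rx laterality MIDLINE but isocenter {abs(offset):.0f} mm off mid-sagittal")
    if problems:
        return CheckResult("rx_site_laterality", CheckStatus.FAIL,
                           "; ".join(problems), observed=offset)
    return CheckResult("rx_site_laterality", CheckStatus.PASS,
                       "site and laterality consistent", observed=offset)


def check_orientation_consistency(plan: TreatmentPlan,
                                  rx: PrescriptionDirective = None,
                                  tol: float = 1e-3) -> CheckResult:
    """CT direction cosines must match the canonical ones for the position."""
    expected = CANONICAL_ORIENTATIONS[plan.patient_position]
    observed = plan.image_orientation
    if len(observed) != 6 or any(abs(o - e) > tol for o, e in zip(observed, expected)):
        return CheckResult(
            "orientation_consistency", CheckStatus.FAIL,
            f"image orientation {tuple(round(v, 3) for v in observed)} inconsistent "
            f"with patient position {plan.patient_position.value} "
            f"(expected {expected})",
            observed=list(observed), expected=list(expected))
    return CheckResult("orientation_consistency", CheckStatus.PASS,
                       "image orientation matches patient position")


def check_user_origin(plan: TreatmentPlan,
                      rx: PrescriptionDirective = None) -> CheckResult:
    """User origin explicitly set and located inside the BODY bounding box."""
    if not plan.user_origin_set:
        return CheckResult("user_origin", CheckStatus.FAIL,
                           "user origin at scanner default (never set)")
    lo, hi = plan.body().bounding_box()
    if np.any(plan.user_origin < lo) or np.any(plan.user_origin > hi):
        return CheckResult(
            "user_origin", CheckStatus.FAIL,
            f"user origin {np.round(plan.user_origin, 1).tolist()} mm lies outside "
            f"the BODY bounding box",
            observed=list(plan.user_origin))
    return CheckResult("user_origin", CheckStatus.PASS,
                       "user origin set and inside BODY")


def check_flags(plan: TreatmentPlan, rx: PrescriptionDirective) -> list[CheckResult]:
    """Special-consideration flags (cardiac device, previous RT, free-text).

    The engine cannot verify the clinical response to a flag — it can only
    force acknowledgement.  True, unacknowledged flags WARN; an entry in the
    directive's ``acknowledged`` list downgrades to PASS with an audit note.
    """
    results = []
    named = [("flag_cardiac_device", "cardiac device", rx.cardiac_device),
             ("flag_previous_rt", "previous RT", rx.previous_rt)]
    for flag in rx.other_flags:
        named.append((f"flag_{_normalize_label(flag)}", flag, True))
    for check_id, label, is_set in named:
        if not is_set:
            results.append(CheckResult(check_id, CheckStatus.PASS,
                                       f"no {label} flag"))
        elif label in rx.acknowledged or check_id in rx.acknowledged:
            results.append(CheckResult(
                check_id, CheckStatus.PASS,
                f"{label} flag acknowledged by reviewer (audit note)"))
        else:
            results.append(CheckResult(
                check_id, CheckStatus.WARN,
                f"{label} flagged — reviewer must confirm it was taken into "
                f"consideration for this plan"))
    return results


def check_mu_sanity(plan: TreatmentPlan, rx: PrescriptionDirective = None,
                    low: float = 0.8, high: float = 5.0) -> CheckResult:
    """Total MU per fraction over dose per fraction within [low, high] MU/cGy.

    Bounds are inclusive; outside them the plan WARNs with the ratio — a
    grossly scaled MU total is the classic hand-calculation catch.
    """
    total_mu = sum(b.monitor_units for b in plan.treatment_beams())
    ratio = total_mu / plan.dose_per_fraction
    if not (low <= ratio <= high):
        return CheckResult(
            "mu_sanity", CheckStatus.WARN,
            f"MU/cGy ratio {ratio:.2f} outside [{low}, {high}] "
            f"({total_mu:g} MU for {plan.dose_per_fraction:g} cGy/fx)",
            observed=ratio, expected=[low, high])
    return CheckResult("mu_sanity", CheckStatus.PASS,
                       f"MU/cGy ratio {ratio:.2f} plausible", observed=ratio)


def structure_dose_values(plan: TreatmentPlan, structure) -> np.ndarray:
    """Dose-grid values (cGy) at voxel centers inside a structure.

    Membership is per-slice point-in-polygon with nearest-slice assignment
    of each contour to a grid plane; nearest-voxel semantics, no
    interpolation.
    """
    grid = plan.dose_grid
    if grid is None:
        raise ValueError("plan has no dose grid")
    zs = grid.z_levels
    values = []
    for contour in structure.contours:
        k = int(np.argmin(np.abs(zs - contour[0, 2])))
        xs, ys = grid.voxel_centers_slice(k)
        xx, yy = np.meshgrid(xs, ys)            # (ny, nx)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        mask = MplPath(contour[:, :2]).contains_points(pts)
        values.append(grid.values[k].ravel()[mask])
    if not values:
        return np.empty(0)
    return np.concatenate(values)


def check_dose_limits(plan: TreatmentPlan, rx: PrescriptionDirective) -> list[CheckResult]:
    """Per-structure MAX/MEAN dose against the directive's OAR limits."""
    check_id = "dose_limits"
    if plan.dose_grid is None:
        return [CheckResult(check_id, CheckStatus.NOT_APPLICABLE,
                            "no dose grid loaded; dose limits not evaluated")]
    if not rx.oar_limits:
        return [CheckResult(check_id, CheckStatus.PASS,
                            "no OAR limits specified in directive")]
    results = []
    for lim in rx.oar_limits:
        matched = [s for s in plan.structures
                   if fnmatch.fnmatch(s.name.casefold(), lim.structure_pattern.casefold())]
        if not matched:
            results.append(CheckResult(
                check_id, CheckStatus.WARN,
                f"no structure matches pattern {lim.structure_pattern!r}"))
            continue
        for s in matched:
            doses = structure_dose_values(plan, s)
            if doses.size == 0:
                results.append(CheckResult(
                    check_id, CheckStatus.WARN,
                    f"{s.name}: no dose voxels inside contours"))
                continue
            value = float(doses.max() if lim.metric == "MAX" else doses.mean())
            if value > lim.limit_cGy:
                results.append(CheckResult(
                    check_id, CheckStatus.FAIL,
                    f"{s.name}: {lim.metric} dose {value:.1f} cGy exceeds limit "
                    f"{lim.limit_cGy:.1f} cGy",
                    observed=value, expected=lim.limit_cGy))
            else:
                results.append(CheckResult(
                    check_id, CheckStatus.PASS,
                    f"{s.name}: {lim.metric} dose {value:.1f} cGy within limit "
                    f"{lim.limit_cGy:.1f} cGy",
                    observed=value, expected=lim.limit_cGy))
    return results


def _beam_axis_patient(gantry_deg: float, position) -> np.ndarray:
    """Unit vector of the beam axis (source->isocenter) in patient coords."""
    from .shift_note import COUCH_ROTATIONS

    g = np.deg2rad(gantry_deg)
    # room frame (LAT, LONG, VERT): gantry 0 points down from above
    axis_room = np.array([np.sin(g), 0.0, -np.cos(g)])
    rot = COUCH_ROTATIONS[position]               # patient -> room
    return rot.T @ axis_room                      # room -> patient


def check_clearance_proxy(plan: TreatmentPlan, rx: PrescriptionDirective = None,
                          clearance_radius_mm: float = 400.0) -> CheckResult:
    """Collision-risk proxy: body extent around the isocenter per beam.

    For each treatment beam, the maximum distance from the isocenter to any
    BODY contour point on the isocenter's slice, measured perpendicular to
    the beam axis.  This is a conservative stand-in for machine-geometry
    collision modelling: a patient edge far from the isocenter in the beam's
    transverse plane is what approaches the gantry.
    """
    tx_beams = plan.treatment_beams()
    if not tx_beams:
        return CheckResult("clearance", CheckStatus.NOT_APPLICABLE,
                           "no treatment beams; clearance proxy not evaluated")
    body = plan.body()
    pts = body.all_points()
    zs = np.array([c[0, 2] for c in body.contours])
    nearest = body.contours[int(np.argmin(np.abs(zs - plan.isocenter[2])))]
    rel = nearest - plan.isocenter
    worst = 0.0
    worst_beam = None
    for b in tx_beams:
        axis = _beam_axis_patient(b.gantry_angle, plan.patient_position)
        perp = rel - np.outer(rel @ axis, axis)
        d = float(np.linalg.norm(perp, axis=1).max())
        if d > worst:
            worst, worst_beam = d, b.beam_id
    if worst > clearance_radius_mm:
        return CheckResult(
            "clearance", CheckStatus.WARN,
            f"beam {worst_beam}: body extends {worst:.0f} mm from isocenter "
            f"(clearance proxy radius {clearance_radius_mm:.0f} mm) — verify "
            f"machine clearance",
            observed=worst, expected=clearance_radius_mm)
    return CheckResult("clearance", CheckStatus.PASS,
                       f"max body extent {worst:.0f} mm within clearance proxy "
                       f"radius {clearance_radius_mm:.0f} mm",
                       observed=worst, expected=clearance_radius_mm)


def _check_shift_note(plan: TreatmentPlan, rx: PrescriptionDirective,
                      tol_cm: float = 0.05) -> CheckResult:
    from .shift_note import verify_shift_note

    if rx.shift_note is None:
        return CheckResult("shift_note", CheckStatus.NOT_APPLICABLE,
                           "no shift note recorded in directive")
    if not plan.user_origin_set:
        return CheckResult("shift_note", CheckStatus.NOT_APPLICABLE,
                           "user origin not set; shifts cannot be computed "
                           "(see user_origin check)")
    return verify_shift_note(rx.shift_note, plan, tol_cm=tol_cm)


# ---------------------------------------------------------------------------
# Registry and runner
# ---------------------------------------------------------------------------

def default_registry() -> CheckRegistry:
    """The concrete high-severity check registry.

    Severity seeds come from committee FMEA scores where published for the
    named item; items without a published severity default to 5.
    """
    C = CheckCategory
    return CheckRegistry([
        CheckItem("rx_site_laterality", C.RX_MATCH, 9.3,
                  lambda p, r, k: check_rx_site_laterality(p, r, **k),
                  params={"lat_tol": 20.0, "laterality_severity": 9.1}),
        CheckItem("orientation_consistency", C.GEOMETRY, 8.4,
                  lambda p, r, k: check_orientation_consistency(p, r, **k),
                  params={"tol": 1e-3}),
        CheckItem("rx_fractionation", C.RX_MATCH, 8.4,
                  lambda p, r, k: check_rx_fractionation(p, r, **k),
                  params={"tol_frac_dose": 0.5}),
        CheckItem("flags", C.FLAGS, 8.0,
                  lambda p, r, k: check_flags(p, r)),
        CheckItem("user_origin", C.GEOMETRY, 8.0,
                  lambda p, r, k: check_user_origin(p, r)),
        CheckItem("shift_note", C.GEOMETRY, 7.9,
                  lambda p, r, k: _check_shift_note(p, r, **k),
                  params={"tol_cm": 0.05}),
        CheckItem("mu_sanity", C.DELIVERY, 7.9,
                  lambda p, r, k: check_mu_sanity(p, r, **k),
                  params={"low": 0.8, "high": 5.0}),
        CheckItem("clearance", C.DELIVERY, 7.3,
                  lambda p, r, k: check_clearance_proxy(p, r, **k),
                  params={"clearance_radius_mm": 400.0}),
        CheckItem("rx_energy_bolus", C.RX_MATCH, 5.0,
                  lambda p, r, k: check_rx_energy_bolus(p, r)),
        CheckItem("dose_limits", C.DOSE, 5.0,
                  lambda p, r, k: check_dose_limits(p, r)),
    ])


def run_checks(plan: TreatmentPlan, rx: PrescriptionDirective,
               registry: Optional[CheckRegistry] = None,
               run_timestamp: Optional[str] = None) -> CheckReport:
    """Execute every enabled check and collect the results.

    Deterministic: rerunning on unchanged inputs yields an identical report
    (the timestamp is caller-supplied, ``None`` by default).  A rule that
    raises is recorded as FAIL with an engine-error message.
    """
    registry = registry or default_registry()
    results: list[CheckResult] = []
    for item in registry:
        if not item.enabled:
            continue
        params = {k: v for k, v in item.params.items()
                  if k not in ("laterality_severity",)}
        try:
            out = item.func(plan, rx, params)
        except Exception as exc:  # noqa: BLE001 — contract: surface, never skip
            out = CheckResult(item.check_id, CheckStatus.FAIL,
                              f"engine error in {item.check_id}: {exc}")
        if isinstance(out, CheckResult):
            out = [out]
        results.extend(out)
    return CheckReport(plan_id=plan.plan_id, results=results,
                       config_fingerprint=registry.fingerprint(),
                       run_timestamp=run_timestamp)
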