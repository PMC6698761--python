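"""Domain model for external-beam treatment plans and prescription directives.

The in-memory types here are the operands of every automated check: a
:class:`TreatmentPlan` normalized from a DICOM RT Plan / RT Structure Set
(and optionally RT Dose) triple, and a :class:`PrescriptionDirective`
carrying the *intended* treatment as recorded in the record-and-verify
system.  The directive lives outside DICOM on purpose — it is the reference
the plan is checked against, so it is stored as a small versioned YAML/JSON
sidecar file rather than read from any vendor database.

Conventions
-----------
* All coordinates are DICOM patient LPS (x → patient left, y → posterior,
  z → superior) in millimetres.
* All doses are centigray (cGy); DICOM Gy values are converted on load.
* Supported patient positions: HFS, HFP, FFS, FFP.  Decubitus and
  multi-isocenter plans are rejected at load — the check semantics do not
  cover them, and a loud failure beats a half-checked plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
import yaml

__all__ = [
    "PatientPosition",
    "StructureRole",
    "Laterality",
    "Beam",
    "Structure",
    "DoseGrid",
    "TreatmentPlan",
    "OARLimit",
    "PrescriptionDirective",
    "PlanLoadError",
    "DirectiveError",
    "CANONICAL_ORIENTATIONS",
    "load_plan",
    "load_directive",
]


class PlanLoadError(ValueError):
    """A DICOM file set could not be normalized into a TreatmentPlan."""


class DirectiveError(ValueError):
    """A prescription directive file is malformed or internally inconsistent."""


class PatientPosition(str, Enum):
    HFS = "HFS"
    HFP = "HFP"
    FFS = "FFS"
    FFP = "FFP"


class StructureRole(str, Enum):
    BODY = "BODY"
    TARGET = "TARGET"
    OAR = "OAR"
    OTHER = "OTHER"


class Laterality(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    MIDLINE = "MIDLINE"
    NA = "NA"


#: Canonical axial image-orientation direction cosines (row, column) implied
#: by each supported patient position.
CANONICAL_ORIENTATIONS: dict[PatientPosition, tuple[float, ...]] = {
    PatientPosition.HFS: (1.0, 0.0, 0.0, 0.0, 1.0, 0.0),
    PatientPosition.HFP: (-1.0, 0.0, 0.0, 0.0, -1.0, 0.0),
    PatientPosition.FFS: (-1.0, 0.0, 0.0, 0.0, 1.0, 0.0),
    PatientPosition.FFP: (1.0, 0.0, 0.0, 0.0, -1.0, 0.0),
}


@dataclass(frozen=True)
class Beam:
    beam_id: str
    energy: str                # field-label style, e.g. "6X", "15X", "6E"
    monitor_units: float       # MU per fraction
    gantry_angle: float        # degrees, [0, 360)
    meterset_weight: float     # fraction of the fraction dose this beam delivers
    is_setup_field: bool = False
    bolus_linked: bool = False


@dataclass(frozen=True)
class Structure:
    name: str
    role: StructureRole
    #: one (N, 3) float array of closed-planar contour points per slice, mm
    contours: tuple[np.ndarray, ...] = ()

    def all_points(self) -> np.ndarray:
        if not self.contours:
            return np.empty((0, 3))
        return np.vstack(self.contours)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = self.all_points()
        if pts.size == 0:
            raise ValueError(f"structure {self.name!r} has no contour points")
        return pts.min(axis=0), pts.max(axis=0)


@dataclass(frozen=True)
class DoseGrid:
    origin: np.ndarray          # (3,) mm, position of first voxel center
    spacing: np.ndarray         # (3,) mm, (dx, dy, dz), strictly positive
    values: np.ndarray          # (nz, ny, nx) cGy

    def __post_init__(self):
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("dose grid spacing must be strictly positive")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("dose grid values must be non-negative")

    def voxel_centers_slice(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate vectors of slice ``k``."""
        nx = self.values.shape[2]
        ny = self.values.shape[1]
        xs = self.origin[0] + np.arange(nx) * self.spacing[0]
        ys = self.origin[1] + np.arange(ny) * self.spacing[1]
        return xs, ys

    @property
    def z_levels(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.values.shape[0]) * self.spacing[2]


@dataclass
class TreatmentPlan:
    plan_id: str
    patient_position: PatientPosition
    image_orientation: tuple[float, ...]     # 6 direction cosines of the CT
    isocenter: np.ndarray                    # (3,) mm, shared by all beams
    user_origin: np.ndarray                  # (3,) mm
    user_origin_set: bool
    beams: list[Beam]
    fractions_planned: int
    dose_per_fraction: float                 # cGy
    total_dose: float                        # cGy
    machine_name: str
    structures: list[Structure]
    dose_grid: Optional[DoseGrid] = None

    def treatment_beams(self) -> list[Beam]:
        return [b for b in self.beams if not b.is_setup_field]

    def structure(self, name: str) -> Optional[Structure]:
        for s in self.structures:
            if s.name == name:
                return s
        return None

    def body(self) -> Structure:
        for s in self.structures:
            if s.role is StructureRole.BODY:
                return s
        raise PlanLoadError("plan has no BODY structure")

    def content_fingerprint(self) -> str:
        """Stable hash of the plan content; used to prove checks never mutate."""
        import hashlib

        h = hashlib.sha256()
        h.update(repr((self.plan_id, self.patient_position.value,
                       self.image_orientation, tuple(self.isocenter),
                       tuple(self.user_origin), self.user_origin_set,
                       self.beams, self.fractions_planned,
                       self.dose_per_fraction, self.total_dose,
                       self.machine_name)).encode())
        for s in self.structures:
            h.update(s.name.encode())
            for c in s.contours:
                h.update(np.ascontiguousarray(c).tobytes())
        if self.dose_grid is not None:
            h.update(np.ascontiguousarray(self.dose_grid.values).tobytes())
            h.update(np.ascontiguousarray(self.dose_grid.origin).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class OARLimit:
    structure_pattern: str      # fnmatch-style, case-insensitive
    metric: str                 # "MAX" or "MEAN"
    limit_cGy: float


@dataclass
class PrescriptionDirective:
    """The intended treatment, as the record-and-verify system holds it."""

    site: str
    total_dose: float            # cGy
    dose_per_fraction: float     # cGy
    fractions: int
    allowed_energies: list[str]
    laterality: Laterality = Laterality.NA
    bolus_required: bool = False
    previous_rt: bool = False
    cardiac_device: bool = False
    other_flags: list[str] = field(default_factory=list)
    acknowledged: list[str] = field(default_factory=list)
    oar_limits: list[OARLimit] = field(default_factory=list)
    shift_note: Optional[str] = None
    user_origin: Optional[Sequence[float]] = None   # fallback when no marker ROI

    def __post_init__(self):
        if self.fractions < 1:
            raise DirectiveError("fractions must be >= 1")
        if abs(self.total_dose - self.fractions * self.dose_per_fraction) > 0.5:
            raise DirectiveError(
                f"directive inconsistent: total_dose {self.total_dose} cGy != "
                f"{self.fractions} x {self.dose_per_fraction} cGy"
            )


# ---------------------------------------------------------------------------
# DICOM readers
# ---------------------------------------------------------------------------

_SUPPORTED_POSITIONS = {p.value for p in PatientPosition}


def _require(ds: pydicom.Dataset, attr: str, context: str):
    if not hasattr(ds, attr):
        raise PlanLoadError(f"missing required DICOM attribute {attr} in {context}")
    return getattr(ds, attr)


def _energy_label(nominal_energy: float, radiation_type: str) -> str:
    suffix = "E" if str(radiation_type).upper() == "ELECTRON" else "X"
    e = float(nominal_energy)
    return f"{int(e) if e == int(e) else e}{suffix}"


def load_plan(rtplan_path, rtstruct_path, rtdose_path=None) -> TreatmentPlan:
    """Normalize one DICOM RT Plan + Structure Set (+ optional Dose) into a
    :class:`TreatmentPlan`.

    Raises :class:`PlanLoadError` naming the offending attribute when a
    required DICOM element is absent, when the frames of reference disagree,
    and for unsupported patient positions or multi-isocenter plans.
    """
    plan_ds = pydicom.dcmread(str(rtplan_path))
    struct_ds = pydicom.dcmread(str(rtstruct_path))

    plan_id = str(_require(plan_ds, "RTPlanLabel", "RT Plan"))

    setup_seq = _require(plan_ds, "PatientSetupSequence", "RT Plan")
    position = str(_require(setup_seq[0], "PatientPosition", "PatientSetupSequence"))
    if position not in _SUPPORTED_POSITIONS:
        raise PlanLoadError(f"unsupported patient position {position!r}")
    position = PatientPosition(position)

    plan_for = str(_require(plan_ds, "FrameOfReferenceUID", "RT Plan"))
    ref_for_seq = _require(struct_ds, "ReferencedFrameOfReferenceSequence", "RT Structure Set")
    struct_for = str(_require(ref_for_seq[0], "FrameOfReferenceUID", "RT Structure Set"))
    if plan_for != struct_for:
        raise PlanLoadError(
            "frame of reference mismatch between RT Plan and RT Structure Set"
        )

    # --- fractionation -----------------------------------------------------
    fg = _require(plan_ds, "FractionGroupSequence", "RT Plan")[0]
    fractions = int(_require(fg, "NumberOfFractionsPlanned", "FractionGroup"))
    dose_ref = _require(plan_ds, "DoseReferenceSequence", "RT Plan")[0]
    total_dose = float(_require(dose_ref, "TargetPrescriptionDose", "DoseReference")) * 100.0

    # per-beam meterset and dose contributions, keyed by beam number
    ref_beams = {int(rb.ReferencedBeamNumber): rb
                 for rb in _require(fg, "ReferencedBeamSequence", "FractionGroup")}

    beams: list[Beam] = []
    isocenters: list[np.ndarray] = []
    beam_doses: dict[str, float] = {}
    for b in _require(plan_ds, "BeamSequence", "RT Plan"):
        number = int(_require(b, "BeamNumber", "Beam"))
        cp0 = _require(b, "ControlPointSequence", f"Beam {number}")[0]
        is_setup = str(getattr(b, "TreatmentDeliveryType", "TREATMENT")).upper() == "SETUP"
        rb = ref_beams.get(number)
        mu = float(getattr(rb, "BeamMeterset", 0.0)) if rb is not None else 0.0
        dose_gy = float(getattr(rb, "BeamDose", 0.0)) if rb is not None else 0.0
        if not is_setup and mu <= 0:
            raise PlanLoadError(f"treatment beam {number} has non-positive BeamMeterset")
        energy = _energy_label(
            _require(cp0, "NominalBeamEnergy", f"Beam {number} control point"),
            getattr(b, "RadiationType", "PHOTON"),
        )
        iso = np.asarray(_require(cp0, "IsocenterPosition", f"Beam {number}"), dtype=float)
        if not is_setup:
            isocenters.append(iso)
        beam_id = str(getattr(b, "BeamName", number))
        beams.append(Beam(
            beam_id=beam_id,
            energy=energy,
            monitor_units=mu,
            gantry_angle=float(getattr(cp0, "GantryAngle", 0.0)) % 360.0,
            meterset_weight=0.0,           # filled below once dpf is known
            is_setup_field=is_setup,
            bolus_linked=bool(getattr(b, "ReferencedBolusSequence", None)),
        ))
        beam_doses[beam_id] = dose_gy

    if not isocenters:
        raise PlanLoadError("plan has no treatment beams")
    iso0 = isocenters[0]
    for iso in isocenters[1:]:
        if np.max(np.abs(iso - iso0)) > 0.01:
            raise PlanLoadError("multi-isocenter plans are not supported")

    dose_per_fraction = 100.0 * sum(
        beam_doses[b.beam_id] for b in beams if not b.is_setup_field
    )
    if dose_per_fraction <= 0:
        raise PlanLoadError("missing required DICOM attribute BeamDose in FractionGroup")
    beams = [
        Beam(
            beam_id=b.beam_id, energy=b.energy, monitor_units=b.monitor_units,
            gantry_angle=b.gantry_angle,
            meterset_weight=(100.0 * beam_doses[b.beam_id] / dose_per_fraction
                             if not b.is_setup_field else 0.0),
            is_setup_field=b.is_setup_field, bolus_linked=b.bolus_linked,
        )
        for b in beams
    ]

    structures, user_origin, user_origin_set = _read_structures(struct_ds)
    if not any(s.role is StructureRole.BODY for s in structures):
        raise PlanLoadError("missing required BODY (EXTERNAL) structure")

    dose_grid = None
    orientation: Optional[tuple[float, ...]] = None
    if rtdose_path is not None:
        dose_grid, orientation = _read_dose(rtdose_path, plan_for)
    if orientation is None and hasattr(struct_ds, "ImageOrientationPatient"):
        orientation = tuple(float(v) for v in struct_ds.ImageOrientationPatient)
    if orientation is None:
        orientation = CANONICAL_ORIENTATIONS[position]

    return TreatmentPlan(
        plan_id=plan_id,
        patient_position=position,
        image_orientation=orientation,
        isocenter=iso0,
        user_origin=user_origin if user_origin is not None else np.zeros(3),
        user_origin_set=user_origin is not None,
        beams=beams,
        fractions_planned=fractions,
        dose_per_fraction=dose_per_fraction,
        total_dose=total_dose,
        machine_name=str(getattr(plan_ds.BeamSequence[0], "TreatmentMachineName", "")),
        structures=structures,
        dose_grid=dose_grid,
    )


_ROLE_FROM_TYPE = {
    "EXTERNAL": StructureRole.BODY,
    "PTV": StructureRole.TARGET,
    "CTV": StructureRole.TARGET,
    "GTV": StructureRole.TARGET,
    "ORGAN": StructureRole.OAR,
}

USER_ORIGIN_ROI_NAME = "UserOrigin"


def _read_structures(struct_ds):
    names = {}
    for roi in _require(struct_ds, "StructureSetROISequence", "RT Structure Set"):
        names[int(roi.ROINumber)] = str(roi.ROIName)
    types = {}
    for obs in getattr(struct_ds, "RTROIObservationsSequence", []):
        types[int(obs.ReferencedROINumber)] = str(
            getattr(obs, "RTROIInterpretedType", "")).upper()

    structures: list[Structure] = []
    user_origin = None
    for rc in getattr(struct_ds, "ROIContourSequence", []):
        num = int(rc.ReferencedROINumber)
        name = names.get(num, f"ROI{num}")
        rtype = types.get(num, "")
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if str(getattr(c, "ContourGeometricType", "")).upper() == "POINT":
                if rtype == "MARKER" or name == USER_ORIGIN_ROI_NAME:
                    user_origin = pts[0]
                continue
            contours.append(pts)
        if rtype == "MARKER" or name == USER_ORIGIN_ROI_NAME:
            continue
        role = _ROLE_FROM_TYPE.get(rtype, StructureRole.OTHER)
        structures.append(Structure(name=name, role=role, contours=tuple(contours)))
    return structures, user_origin, user_origin is not None


def _read_dose(rtdose_path, expected_for: str):
    ds = pydicom.dcmread(str(rtdose_path))
    dose_for = str(getattr(ds, "FrameOfReferenceUID", expected_for))
    if dose_for != expected_for:
        raise PlanLoadError("frame of reference mismatch between RT Plan and RT Dose")
    origin = np.asarray(_require(ds, "ImagePositionPatient", "RT Dose"), dtype=float)
    px = _require(ds, "PixelSpacing", "RT Dose")          # (row=dy, col=dx)
    offsets = np.asarray(_require(ds, "GridFrameOffsetVector", "RT Dose"), dtype=float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    scaling = float(_require(ds, "DoseGridScaling", "RT Dose"))
    values = ds.pixel_array.astype(np.float64) * scaling * 100.0    # Gy -> cGy
    orientation = None
    if hasattr(ds, "ImageOrientationPatient"):
        orientation = tuple(float(v) for v in ds.ImageOrientationPatient)
    grid = DoseGrid(
        origin=origin,
        spacing=np.array([float(px[1]), float(px[0]), dz]),
        values=values,
    )
    return grid, orientation


# ---------------------------------------------------------------------------
# Prescription directive
# ---------------------------------------------------------------------------

def load_directive(path) -> PrescriptionDirective:
    """Load a YAML/JSON prescription directive (schema version 1).

    The directive's own arithmetic is validated: a total dose that is not
    ``fractions x dose_per_fraction`` (within 0.5 cGy) is rejected outright —
    an inconsistent reference cannot anchor any check.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return directive_from_dict(data)


def directive_from_dict(data: dict) -> PrescriptionDirective:
    if not isinstance(data, dict):
        raise DirectiveError("directive must be a mapping")
    if int(data.get("schema", 1)) != 1:
        raise DirectiveError(f"unsupported directive schema {data.get('schema')!r}")
    required = ["site", "total_dose", "dose_per_fraction", "fractions", "allowed_energies"]
    for key in required:
        if key not in data:
            raise DirectiveError(f"directive missing required field {key!r}")
    limits = [
        OARLimit(
            structure_pattern=str(e["structure"]),
            metric=str(e["metric"]).upper(),
            limit_cGy=float(e["limit_cGy"]),
        )
        for e in data.get("oar_limits", [])
    ]
    for lim in limits:
        if lim.metric not in ("MAX", "MEAN"):
            raise DirectiveError(f"unknown OAR limit metric {lim.metric!r}")
    return PrescriptionDirective(
        site=str(data["site"]),
        laterality=Laterality(str(data.get("laterality", "NA")).upper()),
        total_dose=float(data["total_dose"]),
        dose_per_fraction=float(data["dose_per_fraction"]),
        fractions=int(data["fractions"]),
        allowed_energies=[str(e) for e in data["allowed_energies"]],
        bolus_required=bool(data.get("bolus_required", False)),
        previous_rt=bool(data.get("previous_rt", False)),
        cardiac_device=bool(data.get("cardiac_device", False)),
        other_flags=[str(f) for f in data.get("other_flags", [])],
        acknowledged=[str(a) for a in data.get("acknowledged", [])],
        oar_limits=limits,
        shift_note=data.get("shift_note"),
        user_origin=data.get("user_origin"),
    )


def directive_to_dict(rx: PrescriptionDirective) -> dict:
    d = {
        "schema": 1,
        "site": rx.site,
        "laterality": rx.laterality.value,
        "total_dose": rx.total_dose,
        "dose_per_fraction": rx.dose_per_fraction,
        "fractions": rx.fractions,
        "allowed_energies": list(rx.allowed_energies),
        "bolus_required": rx.bolus_required,
        "previous_rt": rx.previous_rt,
        "cardiac_device": rx.cardiac_device,
        "other_flags": list(rx.other_flags),
        "acknowledged": list(rx.acknowledged),
        "oar_limits": [
            {"structure": l.structure_pattern, "metric": l.metric, "limit_cGy": l.limit_cGy}
            for l in rx.oar_limits
        ],
    }
    if rx.shift_note is not None:
        d["shift_note"] = rx.shift_note
    if rx.user_origin is not None:
        d["user_origin"] = [float(v) for v in rx.user_origin]
    return d
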