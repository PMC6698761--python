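"""Synthetic DICOM-RT fixtures and a catalogued error injector.

A plan checker is validated the way the clinic validated its own tool: on
data sets with *known* injected errors (to measure sensitivity / false
negatives) and on clean data (specificity / false positives).  This module
generates geometrically valid plan + structure set + dose + directive
quadruples that are clean by construction, and mutates exactly one targeted
attribute per catalogued error type.

Geometry is deliberately analytic — the body is an elliptic cylinder, the
target and OAR are spheres, the dose grid is painted as a uniform target
level over a uniform background — so every check has a closed-form expected
value.

Determinism: a fixed seed yields a byte-identical file set; simulation runs
derive one child seed per plan from the master seed.
"""

from __future__ import annotations

import copy
import json
import math
import re
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .plan_model import (
    CANONICAL_ORIENTATIONS,
    PatientPosition,
    PrescriptionDirective,
    directive_from_dict,
    directive_to_dict,
    load_directive,
    load_plan,
)

__all__ = [
    "GeneratorParams",
    "PlanFileSet",
    "ErrorSpec",
    "ERROR_CATALOGUE",
    "generate_plan",
    "inject_error",
    "simulate_qa_runs",
]

_RTPLAN_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
_RTSTRUCT_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_FIXED_DATE = "20180101"
_FIXED_TIME = "120000"


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for one synthetic plan.

    Defaults describe a generic conventionally fractionated photon plan:
    2 Gy × 30 to a midline pelvic target on a ~30 × 20 cm elliptic body,
    two 6 MV beams, MU/cGy ratio in the conventional 1–3 range.
    """

    patient_position: str = "HFS"
    site: str = "Pelvis"
    laterality: str = "MIDLINE"
    fractions: int = 30
    dose_per_fraction_cGy: float = 200.0
    energy: str = "6X"
    n_beams: int = 2
    bolus: bool = False
    body_semiaxis_x_mm: float = 150.0
    body_semiaxis_y_mm: float = 100.0
    body_half_length_mm: float = 100.0
    slice_spacing_mm: float = 10.0
    target_radius_mm: float = 30.0
    oar_radius_mm: float = 22.0
    oar_distance_mm: float = 70.0          # OAR center offset from isocenter
    background_dose_fraction: float = 0.3  # background level / prescription
    oar_limit_fraction: float = 0.5        # directive OAR MAX limit / prescription
    machine_name: str = "TrueBeam1"

    @property
    def total_dose_cGy(self) -> float:
        return self.fractions * self.dose_per_fraction_cGy


@dataclass(frozen=True)
class PlanFileSet:
    rtplan: Path
    rtstruct: Path
    rtdose: Path
    directive: Path
    ground_truth: Path

    @classmethod
    def in_dir(cls, d: Path) -> "PlanFileSet":
        d = Path(d)
        return cls(rtplan=d / "rtplan.dcm", rtstruct=d / "rtstruct.dcm",
                   rtdose=d / "rtdose.dcm", directive=d / "directive.yaml",
                   ground_truth=d / "ground_truth.json")

    def load(self):
        plan = load_plan(self.rtplan, self.rtstruct, self.rtdose)
        rx = load_directive(self.directive)
        return plan, rx


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _uid(seed: int, tag: str) -> str:
    return generate_uid(entropy_srcs=[f"planlint.synth.{seed}.{tag}"])


def _signed_uniform(rng, lo: float, hi: float) -> float:
    """Uniform magnitude in [lo, hi] with random sign (never near zero)."""
    return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))


def generate_plan(seed: int, params: Optional[GeneratorParams] = None,
                  out_dir=None) -> tuple[PlanFileSet, PrescriptionDirective, dict]:
    """Write one clean synthetic DICOM plan set + directive + ground truth.

    Deterministic per seed (byte-identical files).  The emitted set is clean
    by construction: every default check passes on it.  Geometry requests
    that cannot be honored (e.g. the OAR would fall outside the body) are
    rejected.
    """
    params = params or GeneratorParams()
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    position = PatientPosition(params.patient_position)
    lat = params.laterality.upper()

    # --- geometry ----------------------------------------------------------
    ax = params.body_semiaxis_x_mm * rng.uniform(0.95, 1.05)
    ay = params.body_semiaxis_y_mm * rng.uniform(0.95, 1.05)
    half_len = params.body_half_length_mm
    dz = params.slice_spacing_mm
    z_slices = np.arange(-half_len, half_len + dz / 2, dz)

    user_origin = np.zeros(3)
    if lat in ("MIDLINE", "NA"):
        iso_x = _signed_uniform(rng, 5.0, 15.0)
    elif lat == "LEFT":
        iso_x = float(rng.uniform(25.0, 60.0))
    elif lat == "RIGHT":
        iso_x = -float(rng.uniform(25.0, 60.0))
    else:
        raise ValueError(f"unknown laterality {lat!r}")
    isocenter = np.array([iso_x,
                          _signed_uniform(rng, 5.0, 30.0),
                          _signed_uniform(rng, 5.0, 30.0)])

    # OAR: pushed from the isocenter toward the body center, far enough from
    # the target sphere that its dose is exactly the background level
    direction = -isocenter[:2]
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-6 else np.array([1.0, 0.0])
    oar_center = np.array([
        isocenter[0] + params.oar_distance_mm * direction[0],
        isocenter[1] + params.oar_distance_mm * direction[1],
        float(np.clip(isocenter[2], -half_len + params.oar_radius_mm + dz,
                      half_len - params.oar_radius_mm - dz)),
    ])
    if params.oar_distance_mm <= params.oar_radius_mm + params.target_radius_mm:
        raise ValueError("OAR would overlap the target sphere")
    r = params.oar_radius_mm
    if ((oar_center[0] / (ax - r)) ** 2 + (oar_center[1] / (ay - r)) ** 2) >= 1.0:
        raise ValueError("requested OAR geometry falls outside the body")

    # --- beams -------------------------------------------------------------
    dpf = params.dose_per_fraction_cGy
    total = params.total_dose_cGy
    mu_ratio = float(rng.uniform(1.0, 3.0))
    total_mu = mu_ratio * dpf
    weights = rng.uniform(0.8, 1.2, size=params.n_beams)
    weights = weights / weights.sum()
    gantry_start = float(rng.uniform(0.0, 360.0))
    gantries = [(gantry_start + i * 360.0 / params.n_beams) % 360.0
                for i in range(params.n_beams)]

    frame_uid = _uid(seed, "frame")

    # --- structures --------------------------------------------------------
    def ellipse(z, a, b, n=32):
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack([a * np.cos(t), b * np.sin(t), np.full(n, z)])

    def sphere_contours(center, radius, n=16):
        out = []
        for z in z_slices:
            h = radius ** 2 - (z - center[2]) ** 2
            if h <= 1.0:       # skip grazing slices: degenerate rings
                continue
            rad = math.sqrt(h)
            t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
            out.append(np.column_stack([center[0] + rad * np.cos(t),
                                        center[1] + rad * np.sin(t),
                                        np.full(n, z)]))
        return out

    body_contours = [ellipse(z, ax, ay) for z in z_slices]
    target_contours = sphere_contours(isocenter, params.target_radius_mm)
    oar_contours = sphere_contours(oar_center, params.oar_radius_mm)

    # --- dose grid ---------------------------------------------------------
    gx, gy, gdz = 8.0, 8.0, dz
    xs = np.arange(-160.0, 160.0 + gx / 2, gx)
    ys = np.arange(-120.0, 120.0 + gy / 2, gy)
    zs = z_slices.copy()
    X, Y = np.meshgrid(xs, ys)                       # (ny, nx)
    dose = np.zeros((len(zs), len(ys), len(xs)))
    bg = params.background_dose_fraction * total
    for k, z in enumerate(zs):
        inside_body = (X / ax) ** 2 + (Y / ay) ** 2 <= 1.0
        plane = np.where(inside_body, bg, 0.0)
        d2 = (X - isocenter[0]) ** 2 + (Y - isocenter[1]) ** 2 + (z - isocenter[2]) ** 2
        plane = np.where(d2 <= params.target_radius_mm ** 2, total, plane)
        dose[k] = plane

    # --- shift note --------------------------------------------------------
    from .shift_note import _instruction_from_displacement

    instruction = _instruction_from_displacement(isocenter - user_origin, position)

    # --- write files -------------------------------------------------------
    fileset = PlanFileSet.in_dir(out_dir)
    # RTPlanLabel has VR SH (16 chars max): keep the seed suffix short
    plan_label = f"{params.site}_{position.value}_{seed % 10000:04d}"
    _write_rtplan(fileset.rtplan, seed, plan_label, position, frame_uid,
                  isocenter, params, total_mu, weights, gantries, dpf, total)
    _write_rtstruct(fileset.rtstruct, seed, frame_uid, body_contours,
                    target_contours, oar_contours, user_origin, params)
    _write_rtdose(fileset.rtdose, seed, frame_uid, position, xs, ys, zs,
                  (gx, gy, gdz), dose)

    rx_dict = {
        "schema": 1,
        "site": params.site,
        "laterality": lat,
        "total_dose": total,
        "dose_per_fraction": dpf,
        "fractions": params.fractions,
        "allowed_energies": [params.energy],
        "bolus_required": params.bolus,
        "previous_rt": False,
        "cardiac_device": False,
        "other_flags": [],
        "acknowledged": [],
        "oar_limits": [{"structure": "OAR*", "metric": "MAX",
                        "limit_cGy": params.oar_limit_fraction * total}],
        "shift_note": instruction.note_text,
    }
    fileset.directive.write_text(yaml.safe_dump(rx_dict, sort_keys=True))
    rx = directive_from_dict(rx_dict)

    truth = {
        "seed": seed,
        "plan_id": plan_label,
        "patient_position": position.value,
        "image_orientation": list(CANONICAL_ORIENTATIONS[position]),
        "isocenter_mm": [float(v) for v in isocenter],
        "user_origin_mm": [float(v) for v in user_origin],
        "fractions": params.fractions,
        "dose_per_fraction_cGy": dpf,
        "total_dose_cGy": total,
        "energy": params.energy,
        "total_mu": total_mu,
        "mu_per_cGy": mu_ratio,
        "beam_weights": [float(w) for w in weights],
        "gantry_angles": gantries,
        "machine_name": params.machine_name,
        "body_semiaxes_mm": [float(ax), float(ay)],
        "body_z_range_mm": [float(z_slices[0]), float(z_slices[-1])],
        "target_radius_mm": params.target_radius_mm,
        "oar_center_mm": [float(v) for v in oar_center],
        "oar_radius_mm": params.oar_radius_mm,
        "background_dose_cGy": bg,
        "oar_limit_cGy": params.oar_limit_fraction * total,
        "shift_note": instruction.note_text,
        "couch_shifts_cm": list(instruction.couch),
    }
    fileset.ground_truth.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return fileset, rx, truth


def _file_meta(sop_class: str, sop_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(seed: int, sop_class: str, tag: str, modality: str) -> Dataset:
    ds = Dataset()
    sop_uid = _uid(seed, tag)
    ds.file_meta = _file_meta(sop_class, sop_uid)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.Modality = modality
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = f"SYN{seed:07d}"
    ds.StudyInstanceUID = _uid(seed, "study")
    ds.SeriesInstanceUID = _uid(seed, f"series.{tag}")
    ds.StudyDate = _FIXED_DATE
    ds.StudyTime = _FIXED_TIME
    ds.Manufacturer = "planlint synthetic"
    return ds


def _write_rtplan(path, seed, label, position, frame_uid, isocenter, params,
                  total_mu, weights, gantries, dpf, total):
    ds = _base_dataset(seed, _RTPLAN_CLASS, "rtplan", "RTPLAN")
    ds.RTPlanLabel = label
    ds.RTPlanDate = _FIXED_DATE
    ds.FrameOfReferenceUID = frame_uid

    setup = Dataset()
    setup.PatientSetupNumber = 1
    setup.PatientPosition = position.value
    ds.PatientSetupSequence = [setup]

    dose_ref = Dataset()
    dose_ref.DoseReferenceNumber = 1
    dose_ref.DoseReferenceStructureType = "SITE"
    dose_ref.DoseReferenceType = "TARGET"
    dose_ref.TargetPrescriptionDose = total / 100.0      # Gy
    ds.DoseReferenceSequence = [dose_ref]

    n = params.n_beams
    beams = []
    ref_beams = []
    for i in range(n):
        b = Dataset()
        b.BeamNumber = i + 1
        b.BeamName = f"Field{i + 1}"
        b.RadiationType = "ELECTRON" if params.energy.endswith("E") else "PHOTON"
        b.TreatmentDeliveryType = "TREATMENT"
        b.TreatmentMachineName = params.machine_name
        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.NominalBeamEnergy = float(params.energy.rstrip("XE"))
        cp.GantryAngle = gantries[i]
        cp.IsocenterPosition = [float(v) for v in isocenter]
        b.ControlPointSequence = [cp]
        if params.bolus:
            bolus_ref = Dataset()
            bolus_ref.ReferencedROINumber = 99
            b.ReferencedBolusSequence = [bolus_ref]
        beams.append(b)

        rb = Dataset()
        rb.ReferencedBeamNumber = i + 1
        rb.BeamMeterset = float(total_mu * weights[i])
        rb.BeamDose = float(dpf * weights[i] / 100.0)    # Gy
        ref_beams.append(rb)

    # one setup (imaging) field with zero meterset
    sb = Dataset()
    sb.BeamNumber = n + 1
    sb.BeamName = "Setup"
    sb.RadiationType = "PHOTON"
    sb.TreatmentDeliveryType = "SETUP"
    sb.TreatmentMachineName = params.machine_name
    scp = Dataset()
    scp.ControlPointIndex = 0
    scp.NominalBeamEnergy = float(params.energy.rstrip("XE"))
    scp.GantryAngle = 0.0
    scp.IsocenterPosition = [float(v) for v in isocenter]
    sb.ControlPointSequence = [scp]
    beams.append(sb)
    srb = Dataset()
    srb.ReferencedBeamNumber = n + 1
    srb.BeamMeterset = 0.0
    srb.BeamDose = 0.0
    ref_beams.append(srb)

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = params.fractions
    fg.NumberOfBeams = len(beams)
    fg.ReferencedBeamSequence = ref_beams
    ds.FractionGroupSequence = [fg]
    ds.BeamSequence = beams
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def _write_rtstruct(path, seed, frame_uid, body_contours, target_contours,
                    oar_contours, user_origin, params):
    ds = _base_dataset(seed, _RTSTRUCT_CLASS, "rtstruct", "RTSTRUCT")
    ds.StructureSetLabel = "Synthetic"
    ds.StructureSetDate = _FIXED_DATE
    ref_for = Dataset()
    ref_for.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_for]

    rois = [
        (1, "BODY", "EXTERNAL", body_contours, "CLOSED_PLANAR"),
        (2, f"PTV_{params.site}", "PTV", target_contours, "CLOSED_PLANAR"),
        (3, "OAR_Sphere", "ORGAN", oar_contours, "CLOSED_PLANAR"),
        (4, "UserOrigin", "MARKER", [np.array([user_origin])], "POINT"),
    ]
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for num, name, rtype, contours, geom in rois:
        sroi = Dataset()
        sroi.ROINumber = num
        sroi.ROIName = name
        sroi.ReferencedFrameOfReferenceUID = frame_uid
        sroi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(sroi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for pts in contours:
            c = Dataset()
            c.ContourGeometricType = geom
            c.NumberOfContourPoints = len(pts)
            c.ContourData = [float(round(v, 6)) for v in np.asarray(pts).ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = num
        obs.ReferencedROINumber = num
        obs.RTROIInterpretedType = rtype
        ds.RTROIObservationsSequence.append(obs)
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def _write_rtdose(path, seed, frame_uid, position, xs, ys, zs, spacing, dose_cGy):
    ds = _base_dataset(seed, _RTDOSE_CLASS, "rtdose", "RTDOSE")
    ds.FrameOfReferenceUID = frame_uid
    ds.ImagePositionPatient = [float(xs[0]), float(ys[0]), float(zs[0])]
    ds.ImageOrientationPatient = [float(v) for v in CANONICAL_ORIENTATIONS[position]]
    ds.PixelSpacing = [float(spacing[1]), float(spacing[0])]     # (row=dy, col=dx)
    ds.GridFrameOffsetVector = [float(z - zs[0]) for z in zs]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = len(ys)
    ds.Columns = len(xs)
    ds.NumberOfFrames = len(zs)
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    scaling = 1e-4                                               # Gy per stored unit
    ds.DoseGridScaling = scaling
    stored = np.round(dose_cGy / 100.0 / scaling).astype(np.uint32)
    ds.PixelData = stored.tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorSpec:
    """One injectable defect: what to corrupt, by how much, under which seed."""

    error_type: str
    magnitude: Optional[float | str] = None
    seed: int = 0

    @property
    def expected_check(self) -> str:
        return ERROR_CATALOGUE[self.error_type].expected_check

    def resolved_magnitude(self):
        entry = ERROR_CATALOGUE[self.error_type]
        return self.magnitude if self.magnitude is not None else entry.default_magnitude


@dataclass(frozen=True)
class _CatalogueEntry:
    expected_check: str
    default_magnitude: Optional[float | str]
    mutate: Callable[[PlanFileSet, object], None]


def _edit_dicom(path: Path, fn) -> None:
    ds = pydicom.dcmread(str(path))
    fn(ds)
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def _edit_directive(path: Path, fn) -> None:
    data = yaml.safe_load(path.read_text())
    fn(data)
    path.write_text(yaml.safe_dump(data, sort_keys=True))


def _treatment_beams(ds) -> list:
    return [b for b in ds.BeamSequence
            if str(getattr(b, "TreatmentDeliveryType", "TREATMENT")).upper() != "SETUP"]


def _mut_dose_per_fraction(fs: PlanFileSet, mag) -> None:
    # scale every treatment beam's fraction dose so dpf shifts by `mag` cGy
    def fn(ds):
        fg = ds.FractionGroupSequence[0]
        doses = [float(rb.BeamDose) for rb in fg.ReferencedBeamSequence]
        dpf = sum(doses) * 100.0
        factor = (dpf + float(mag)) / dpf
        for rb in fg.ReferencedBeamSequence:
            rb.BeamDose = float(rb.BeamDose) * factor
    _edit_dicom(fs.rtplan, fn)


def _mut_total_dose(fs: PlanFileSet, mag) -> None:
    def fn(ds):
        dr = ds.DoseReferenceSequence[0]
        dr.TargetPrescriptionDose = float(dr.TargetPrescriptionDose) + float(mag) / 100.0
    _edit_dicom(fs.rtplan, fn)


def _mut_fractions(fs: PlanFileSet, mag) -> None:
    def fn(ds):
        fg = ds.FractionGroupSequence[0]
        fg.NumberOfFractionsPlanned = int(fg.NumberOfFractionsPlanned) + int(mag)
    _edit_dicom(fs.rtplan, fn)


def _mut_energy(fs: PlanFileSet, mag) -> None:
    def fn(ds):
        beam = _treatment_beams(ds)[0]
        beam.ControlPointSequence[0].NominalBeamEnergy = float(mag)
    _edit_dicom(fs.rtplan, fn)


def _mut_bolus_missing(fs: PlanFileSet, mag) -> None:
    # prescription requires bolus; the plan links none
    _edit_directive(fs.directive, lambda d: d.__setitem__("bolus_required", True))


def _mut_bolus_extra(fs: PlanFileSet, mag) -> None:
    def fn(ds):
        for beam in _treatment_beams(ds):
            ref = Dataset()
            ref.ReferencedROINumber = 99
            beam.ReferencedBolusSequence = [ref]
    _edit_dicom(fs.rtplan, fn)


def _flip_word(note: str, axis: str, swap: dict[str, str]) -> str:
    lines = []
    for line in note.splitlines():
        if line.strip().upper().startswith(axis + ":"):
            for a, b in swap.items():
                if re.search(rf"\b{a}\b", line):
                    line = re.sub(rf"\b{a}\b", b, line)
                    break
        lines.append(line)
    return "\n".join(lines)


def _mut_shift_sign_flip(fs: PlanFileSet, mag) -> None:
    def fn(d):
        d["shift_note"] = _flip_word(
            d["shift_note"], "VERT",
            {"ANT": "POST", "POST": "ANT"})
    _edit_directive(fs.directive, fn)


def _mut_shift_value(fs: PlanFileSet, mag) -> None:
    def fn(d):
        def bump(m):
            return f"{float(m.group(1)) + float(mag):+.1f}"
        lines = []
        for line in d["shift_note"].splitlines():
            if line.strip().upper().startswith("LAT:"):
                line = re.sub(r"([+-]?\d+(?:\.\d+)?)", bump, line, count=1)
            lines.append(line)
        d["shift_note"] = "\n".join(lines)
    _edit_directive(fs.directive, fn)


def _mut_user_origin_unset(fs: PlanFileSet, mag) -> None:
    def fn(ds):
        keep = [int(r.ROINumber) for r in ds.StructureSetROISequence
                if str(r.ROIName) != "UserOrigin"]
        ds.StructureSetROISequence = [r for r in ds.StructureSetROISequence
                                      if int(r.ROINumber) in keep]
        ds.ROIContourSequence = [r for r in ds.ROIContourSequence
                                 if int(r.ReferencedROINumber) in keep]
        ds.RTROIObservationsSequence = [r for r in ds.RTROIObservationsSequence
                                        if int(r.ReferencedROINumber) in keep]
    _edit_dicom(fs.rtstruct, fn)


def _mut_orientation(fs: PlanFileSet, mag) -> None:
    # negate the row cosines: yields the canonical triple of a different position
    def fn(ds):
        iop = [float(v) for v in ds.ImageOrientationPatient]
        ds.ImageOrientationPatient = [-iop[0], -iop[1], -iop[2]] + iop[3:]
    _edit_dicom(fs.rtdose, fn)


def _mut_mu_scale(fs: PlanFileSet, mag) -> None:
    def fn(ds):
        fg = ds.FractionGroupSequence[0]
        for rb in fg.ReferencedBeamSequence:
            rb.BeamMeterset = float(rb.BeamMeterset) * float(mag)
    _edit_dicom(fs.rtplan, fn)


def _mut_flag(fs: PlanFileSet, mag) -> None:
    _edit_directive(fs.directive, lambda d: d.__setitem__("cardiac_device", True))


def _mut_oar_limit(fs: PlanFileSet, mag) -> None:
    # tighten the OAR limit below the delivered background dose: the plan
    # now exceeds its directive limit
    def fn(d):
        total = float(d["total_dose"])
        for lim in d["oar_limits"]:
            lim["limit_cGy"] = float(mag) * total
    _edit_directive(fs.directive, fn)


#: the 13-entry injectable-defect catalogue; each entry names the one check
#: that must flag it
ERROR_CATALOGUE: dict[str, _CatalogueEntry] = {
    "dose_per_fraction_wrong": _CatalogueEntry("rx_fractionation", -20.0, _mut_dose_per_fraction),
    "total_dose_wrong": _CatalogueEntry("rx_fractionation", 600.0, _mut_total_dose),
    "fractions_wrong": _CatalogueEntry("rx_fractionation", 3, _mut_fractions),
    "energy_wrong": _CatalogueEntry("rx_energy_bolus", 15.0, _mut_energy),
    "bolus_missing": _CatalogueEntry("rx_energy_bolus", None, _mut_bolus_missing),
    "bolus_extra": _CatalogueEntry("rx_energy_bolus", None, _mut_bolus_extra),
    "shift_sign_flip": _CatalogueEntry("shift_note", None, _mut_shift_sign_flip),
    "shift_value_wrong": _CatalogueEntry("shift_note", 1.0, _mut_shift_value),
    "user_origin_unset": _CatalogueEntry("user_origin", None, _mut_user_origin_unset),
    "orientation_mismatch": _CatalogueEntry("orientation_consistency", None, _mut_orientation),
    "mu_scale_error": _CatalogueEntry("mu_sanity", 10.0, _mut_mu_scale),
    "flag_unacknowledged": _CatalogueEntry("flag_cardiac_device", None, _mut_flag),
    "oar_limit_exceeded": _CatalogueEntry("dose_limits", 0.2, _mut_oar_limit),
}

#: checks whose status legitimately co-moves with an injected error type
#: (e.g. removing the user origin makes the shift note unverifiable)
COUPLED_CHECKS: dict[str, set[str]] = {
    "user_origin_unset": {"shift_note"},
}


def inject_error(fileset: PlanFileSet, spec: ErrorSpec, out_dir) -> tuple[PlanFileSet, dict]:
    """Copy a file set and corrupt exactly the attribute the spec targets.

    Returns the mutated file set and a label recording what was injected and
    which check must flag it.
    """
    if spec.error_type not in ERROR_CATALOGUE:
        raise KeyError(f"unknown error type {spec.error_type!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mutated = PlanFileSet.in_dir(out_dir)
    for src, dst in [(fileset.rtplan, mutated.rtplan),
                     (fileset.rtstruct, mutated.rtstruct),
                     (fileset.rtdose, mutated.rtdose),
                     (fileset.directive, mutated.directive),
                     (fileset.ground_truth, mutated.ground_truth)]:
        if Path(src).exists():
            shutil.copyfile(src, dst)
    entry = ERROR_CATALOGUE[spec.error_type]
    entry.mutate(mutated, spec.resolved_magnitude())
    label = {"error_type": spec.error_type,
             "expected_check": entry.expected_check,
             "magnitude": spec.resolved_magnitude(),
             "seed": spec.seed}
    return mutated, label


# ---------------------------------------------------------------------------
# QA-cycle simulation
# ---------------------------------------------------------------------------

def _child_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence([master, index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_qa_runs(n_plans: int, error_mix: dict[str, float], fix_prob: float,
                     seed: int, workdir=None, db=None):
    """Simulate the check–fix–recheck cycle over a cohort of plans.

    Per plan: a clean plan is generated, each catalogue error is injected
    independently with its mix probability, the first check run is recorded;
    every *caught* error (its designated check flagged) is then fixed with
    probability ``fix_prob`` and the final run recorded.  Plans with no
    injected error have a single run that is both first and final.

    Returns an :class:`~planlint.audit_reporting.AuditDB` of all runs.
    """
    import tempfile

    from .audit_reporting import AuditDB, record_run
    from .check_engine import CheckStatus, run_checks

    unknown = set(error_mix) - set(ERROR_CATALOGUE)
    if unknown:
        raise KeyError(f"unknown error types in mix: {sorted(unknown)}")
    if not (0.0 <= fix_prob <= 1.0):
        raise ValueError("fix_prob must lie in [0, 1]")
    if db is None:
        db = AuditDB()

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA0D17]))

    def run_on(fs: PlanFileSet):
        plan, rx = fs.load()
        return run_checks(plan, rx)

    for i in range(n_plans):
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            # audit key: the cohort index (plan labels may repeat across seeds)
            plan_id = f"sim{i:06d}"
            clean, _, _ = generate_plan(_child_seed(seed, i), out_dir=tmp / "clean")
            injected = [etype for etype, p in sorted(error_mix.items())
                        if p > 0 and rng.random() < p]

            current = clean
            for j, etype in enumerate(injected):
                current, _ = inject_error(
                    current, ErrorSpec(etype, seed=_child_seed(seed, i)),
                    tmp / f"err{j}")
            first = run_on(current)
            record_run(db, plan_id, first)

            if injected:
                caught = [e for e in injected
                          if first.worst_status(ERROR_CATALOGUE[e].expected_check)
                          in (CheckStatus.FAIL, CheckStatus.WARN)]
                fixed = {e for e in caught if rng.random() < fix_prob}
                remaining = [e for e in injected if e not in fixed]
                current = clean
                for j, etype in enumerate(remaining):
                    current, _ = inject_error(
                        current, ErrorSpec(etype, seed=_child_seed(seed, i)),
                        tmp / f"fix{j}")
                final = run_on(current)
                record_run(db, plan_id, final)
    return db
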