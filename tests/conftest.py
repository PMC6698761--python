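import numpy as np
import pytest

from planlint.plan_model import (
    Beam,
    DoseGrid,
    Laterality,
    PatientPosition,
    PrescriptionDirective,
    Structure,
    StructureRole,
    TreatmentPlan,
)
from planlint.synthetic_data import generate_plan


@pytest.fixture(scope="session")
def clean_fileset(tmp_path_factory):
    """One clean synthetic DICOM plan set, generated once per session."""
    out = tmp_path_factory.mktemp("clean_plan")
    fileset, rx, truth = generate_plan(7, out_dir=out)
    return fileset, rx, truth


@pytest.fixture(scope="session")
def clean_plan(clean_fileset):
    fileset, _, truth = clean_fileset
    plan, rx = fileset.load()
    return plan, rx, truth


def cylinder_contours(ax=150.0, ay=100.0, zs=range(-100, 101, 20), n=24):
    out = []
    for z in zs:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        out.append(np.column_stack([ax * np.cos(t), ay * np.sin(t),
                                    np.full(n, float(z))]))
    return tuple(out)


def build_plan(
    plan_id="Pelvis_test",
    position="HFS",
    orientation=None,
    isocenter=(0.0, 0.0, 0.0),
    user_origin=(0.0, 0.0, 0.0),
    user_origin_set=True,
    fractions=30,
    dose_per_fraction=200.0,
    total_dose=None,
    beams=None,
    structures=None,
    dose_grid=None,
):
    """In-memory TreatmentPlan for unit tests (no DICOM round trip)."""
    position = PatientPosition(position)
    if orientation is None:
        from planlint.plan_model import CANONICAL_ORIENTATIONS
        orientation = CANONICAL_ORIENTATIONS[position]
    if beams is None:
        beams = [
            Beam("F1", "6X", 200.0, 0.0, 0.5),
            Beam("F2", "6X", 200.0, 180.0, 0.5),
        ]
    if structures is None:
        structures = [Structure("BODY", StructureRole.BODY, cylinder_contours())]
    if total_dose is None:
        total_dose = fractions * dose_per_fraction
    return TreatmentPlan(
        plan_id=plan_id,
        patient_position=position,
        image_orientation=tuple(orientation),
        isocenter=np.asarray(isocenter, dtype=float),
        user_origin=np.asarray(user_origin, dtype=float),
        user_origin_set=user_origin_set,
        beams=list(beams),
        fractions_planned=fractions,
        dose_per_fraction=dose_per_fraction,
        total_dose=total_dose,
        machine_name="TrueBeam1",
        structures=list(structures),
        dose_grid=dose_grid,
    )


def build_rx(
    site="Pelvis",
    laterality="NA",
    fractions=30,
    dose_per_fraction=200.0,
    total_dose=None,
    allowed_energies=("6X",),
    **kwargs,
):
    if total_dose is None:
        total_dose = fractions * dose_per_fraction
    return PrescriptionDirective(
        site=site,
        laterality=Laterality(laterality),
        total_dose=total_dose,
        dose_per_fraction=dose_per_fraction,
        fractions=fractions,
        allowed_energies=list(allowed_energies),
        **kwargs,
    )


def uniform_dose_grid(value_cGy=200.0, shape=(11, 21, 31), spacing=(10.0, 10.0, 20.0),
                      origin=(-150.0, -100.0, -100.0)):
    return DoseGrid(origin=np.asarray(origin, float),
                    spacing=np.asarray(spacing, float),
                    values=np.full(shape, float(value_cGy)))
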