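"""Unit tests for the individual check rules and the runner contract."""

import numpy as np
import pytest

from planlint.check_engine import (
    CheckItem,
    CheckCategory,
    CheckRegistry,
    CheckReport,
    CheckResult,
    CheckStatus,
    check_clearance_proxy,
    check_dose_limits,
    check_flags,
    check_mu_sanity,
    check_orientation_consistency,
    check_rx_energy_bolus,
    check_rx_fractionation,
    check_rx_site_laterality,
    check_user_origin,
    default_registry,
    run_checks,
    structure_dose_values,
)
from planlint.plan_model import Beam, DoseGrid, OARLimit, Structure, StructureRole

from conftest import build_plan, build_rx, cylinder_contours, uniform_dose_grid


class TestRxFractionation:
    def test_matching_passes(self):
        r = check_rx_fractionation(build_plan(), build_rx())
        assert r.status is CheckStatus.PASS

    def test_dose_per_fraction_mismatch_names_both_values(self):
        r = check_rx_fractionation(build_plan(dose_per_fraction=180.0,
                                              total_dose=6000.0), build_rx())
        assert r.status is CheckStatus.FAIL
        assert "dose per fraction" in r.message
        assert "180" in r.message and "200" in r.message

    @pytest.mark.parametrize("plan_kw, expected_terms", [
        ({"fractions": 33, "total_dose": 6000.0}, ["fractions"]),
        ({"fractions": 33}, ["fractions", "total dose"]),
        ({"total_dose": 6600.0}, ["total dose"]),
        ({"dose_per_fraction": 150.0, "total_dose": 4500.0},
         ["dose per fraction", "total dose"]),
    ])
    def test_three_sub_comparisons_enumerated(self, plan_kw, expected_terms):
        """The message names exactly the mismatched quantities, per an
        independent enumeration of the three sub-comparisons."""
        plan = build_plan(**plan_kw)
        rx = build_rx()
        # independent enumeration
        expect = []
        if plan.fractions_planned != rx.fractions:
            expect.append("fractions")
        if abs(plan.dose_per_fraction - rx.dose_per_fraction) > 0.5:
            expect.append("dose per fraction")
        if abs(plan.total_dose - rx.total_dose) > 0.5:
            expect.append("total dose")
        assert expect == expected_terms
        r = check_rx_fractionation(plan, rx)
        assert r.status is CheckStatus.FAIL
        for term in ("fractions", "dose per fraction", "total dose"):
            assert (term in r.message) == (term in expected_terms)

    def test_within_tolerance_passes(self):
        r = check_rx_fractionation(build_plan(total_dose=6000.4), build_rx())
        assert r.status is CheckStatus.PASS


class TestRxEnergyBolus:
    def test_allowed_energy_no_bolus_passes(self):
        assert check_rx_energy_bolus(build_plan(), build_rx()).status is CheckStatus.PASS

    def test_disallowed_energy_names_beam(self):
        beams = [Beam("F1", "6X", 200, 0, 0.5), Beam("F2", "15X", 200, 180, 0.5)]
        r = check_rx_energy_bolus(build_plan(beams=beams), build_rx())
        assert r.status is CheckStatus.FAIL
        assert "F2" in r.message and "15X" in r.message

    def test_bolus_prescribed_but_missing(self):
        r = check_rx_energy_bolus(build_plan(), build_rx(bolus_required=True))
        assert r.status is CheckStatus.FAIL
        assert "bolus prescribed but not linked" in r.message

    def test_bolus_linked_but_not_prescribed(self):
        beams = [Beam("F1", "6X", 400, 0, 1.0, bolus_linked=True)]
        r = check_rx_energy_bolus(build_plan(beams=beams), build_rx())
        assert r.status is CheckStatus.FAIL
        assert "not prescribed" in r.message

    def test_setup_field_energy_ignored(self):
        beams = [Beam("F1", "6X", 400, 0, 1.0),
                 Beam("Setup", "15X", 0, 0, 0.0, is_setup_field=True)]
        assert check_rx_energy_bolus(build_plan(beams=beams),
                                     build_rx()).status is CheckStatus.PASS


class TestSiteLaterality:
    def test_left_isocenter_on_left_passes(self):
        r = check_rx_site_laterality(build_plan(isocenter=(45, 0, 0)),
                                     build_rx(laterality="LEFT"))
        assert r.status is CheckStatus.PASS

    def test_left_isocenter_on_right_fails(self):
        r = check_rx_site_laterality(build_plan(isocenter=(-45, 0, 0)),
                                     build_rx(laterality="LEFT"))
        assert r.status is CheckStatus.FAIL

    def test_midline_small_offset_passes(self):
        # body centroid sits at x=0 by construction, so offset is exactly -8 mm
        plan = build_plan(isocenter=(-8.0, 0, 0))
        body = plan.body()
        assert body.all_points()[:, 0].mean() == pytest.approx(0.0, abs=1e-9)
        r = check_rx_site_laterality(plan, build_rx(laterality="MIDLINE"))
        assert r.status is CheckStatus.PASS
        assert r.observed == pytest.approx(-8.0, abs=1e-9)

    def test_midline_large_offset_fails(self):
        r = check_rx_site_laterality(build_plan(isocenter=(35, 0, 0)),
                                     build_rx(laterality="MIDLINE"))
        assert r.status is CheckStatus.FAIL

    def test_site_token_not_in_label_fails(self):
        r = check_rx_site_laterality(build_plan(plan_id="Thorax_test"),
                                     build_rx(site="Pelvis"))
        assert r.status is CheckStatus.FAIL
        assert "Pelvis" in r.message

    def test_site_matching_ignores_case_and_punctuation(self):
        r = check_rx_site_laterality(build_plan(plan_id="LT-BREAST_3DCRT"),
                                     build_rx(site="Lt Breast"))
        assert r.status is CheckStatus.PASS


class TestOrientation:
    @pytest.mark.parametrize("position, cosines", [
        ("HFS", (1, 0, 0, 0, 1, 0)),
        ("HFP", (-1, 0, 0, 0, -1, 0)),
        ("FFS", (-1, 0, 0, 0, 1, 0)),
        ("FFP", (1, 0, 0, 0, -1, 0)),
    ])
    def test_canonical_cosines_pass(self, position, cosines):
        r = check_orientation_consistency(
            build_plan(position=position, orientation=cosines))
        assert r.status is CheckStatus.PASS

    def test_hfp_cosines_are_hfs_rotated_half_turn_about_z(self):
        """Canonical HFP cosines equal a 180-degree rotation about z applied
        to the HFS cosines (independent construction)."""
        rot = np.array([[-1, 0, 0], [0, -1, 0], [0, 0, 1]], dtype=float)
        hfs_row, hfs_col = np.array([1, 0, 0.0]), np.array([0, 1, 0.0])
        expected = tuple(rot @ hfs_row) + tuple(rot @ hfs_col)
        r = check_orientation_consistency(
            build_plan(position="HFP", orientation=expected))
        assert r.status is CheckStatus.PASS

    def test_position_label_contradicting_cosines_fails(self):
        r = check_orientation_consistency(
            build_plan(position="FFS", orientation=(1, 0, 0, 0, 1, 0)))
        assert r.status is CheckStatus.FAIL
        assert "FFS" in r.message


class TestUserOrigin:
    def test_origin_inside_body_passes(self):
        assert check_user_origin(build_plan()).status is CheckStatus.PASS

    def test_unset_origin_fails(self):
        r = check_user_origin(build_plan(user_origin_set=False))
        assert r.status is CheckStatus.FAIL
        assert "scanner default" in r.message

    def test_origin_far_outside_body_fails(self):
        # body spans z in [-100, 100]; 400 mm superior is far outside the box
        plan = build_plan(user_origin=(0, 0, 500.0))
        lo, hi = plan.body().bounding_box()
        assert 500.0 > hi[2]
        assert check_user_origin(plan).status is CheckStatus.FAIL


class TestFlags:
    def test_all_flags_false_gives_two_pass_entries(self):
        results = check_flags(build_plan(), build_rx())
        assert [r.status for r in results] == [CheckStatus.PASS] * 2
        assert {r.check_id for r in results} == {"flag_cardiac_device",
                                                 "flag_previous_rt"}

    def test_unacknowledged_flag_warns(self):
        results = check_flags(build_plan(), build_rx(cardiac_device=True))
        by_id = {r.check_id: r for r in results}
        assert by_id["flag_cardiac_device"].status is CheckStatus.WARN

    def test_acknowledged_flag_passes_with_audit_note(self):
        results = check_flags(build_plan(), build_rx(
            cardiac_device=True, acknowledged=["cardiac device"]))
        by_id = {r.check_id: r for r in results}
        assert by_id["flag_cardiac_device"].status is CheckStatus.PASS
        assert "acknowledged" in by_id["flag_cardiac_device"].message

    def test_other_flags_produce_entries(self):
        results = check_flags(build_plan(), build_rx(other_flags=["fetus"]))
        assert any(r.check_id == "flag_fetus" and r.status is CheckStatus.WARN
                   for r in results)


class TestMuSanity:
    def test_typical_ratio_passes(self):
        # 400 MU total for 200 cGy/fx: ratio 2.0
        r = check_mu_sanity(build_plan())
        assert r.status is CheckStatus.PASS
        assert r.observed == pytest.approx(2.0)

    def test_grossly_scaled_mu_warns_with_ratio(self):
        beams = [Beam("F1", "6X", 4000.0, 0, 1.0)]
        r = check_mu_sanity(build_plan(beams=beams))
        assert r.status is CheckStatus.WARN
        assert r.observed == pytest.approx(20.0)

    @pytest.mark.parametrize("total_mu, status", [
        (160.0, CheckStatus.PASS),       # ratio exactly 0.8: inclusive bound
        (1000.0, CheckStatus.PASS),      # ratio exactly 5.0
        (159.0, CheckStatus.WARN),
        (1001.0, CheckStatus.WARN),
    ])
    def test_bounds_inclusive(self, total_mu, status):
        beams = [Beam("F1", "6X", total_mu, 0, 1.0)]
        assert check_mu_sanity(build_plan(beams=beams)).status is status


class TestDoseLimits:
    def _oar_sphere(self, center=(0.0, 0.0, 0.0), radius=40.0, n=64):
        contours = []
        for z in np.arange(-100.0, 101.0, 20.0):
            h = radius ** 2 - (z - center[2]) ** 2
            if h <= 0:
                continue
            r = np.sqrt(h)
            t = np.linspace(0, 2 * np.pi, n, endpoint=False)
            contours.append(np.column_stack([
                center[0] + r * np.cos(t), center[1] + r * np.sin(t),
                np.full(n, z)]))
        return Structure("OAR_test", StructureRole.OAR, tuple(contours))

    def test_uniform_grid_mean_within_limit_passes(self):
        plan = build_plan(dose_grid=uniform_dose_grid(200.0),
                          structures=[Structure("BODY", StructureRole.BODY,
                                                cylinder_contours()),
                                      self._oar_sphere()])
        rx = build_rx(oar_limits=[OARLimit("OAR*", "MEAN", 300.0)])
        results = check_dose_limits(plan, rx)
        oar = [r for r in results if "OAR_test" in r.message]
        assert len(oar) == 1 and oar[0].status is CheckStatus.PASS
        assert oar[0].observed == pytest.approx(200.0)

    def test_uniform_grid_max_over_limit_fails(self):
        plan = build_plan(dose_grid=uniform_dose_grid(200.0),
                          structures=[Structure("BODY", StructureRole.BODY,
                                                cylinder_contours()),
                                      self._oar_sphere()])
        rx = build_rx(oar_limits=[OARLimit("OAR*", "MAX", 100.0)])
        oar = [r for r in check_dose_limits(plan, rx) if "OAR_test" in r.message]
        assert oar[0].status is CheckStatus.FAIL
        assert oar[0].observed == pytest.approx(200.0)

    def test_half_dosed_sphere_mean_matches_brute_force_oracle(self):
        """Sphere straddling a 100-cGy / 0-cGy boundary: MEAN from the engine
        equals a brute-force per-slice point-in-circle oracle, and is ~50."""
        grid = uniform_dose_grid(0.0, shape=(11, 41, 61), spacing=(5.0, 5.0, 20.0),
                                 origin=(-147.5, -97.5, -100.0))
        values = grid.values.copy()
        xs = grid.origin[0] + np.arange(values.shape[2]) * grid.spacing[0]
        values[:, :, xs < 0.0] = 100.0
        grid = DoseGrid(grid.origin, grid.spacing, values)
        sphere = self._oar_sphere(center=(0.0, 0.0, 0.0), radius=45.0)
        plan = build_plan(dose_grid=grid,
                          structures=[Structure("BODY", StructureRole.BODY,
                                                cylinder_contours()), sphere])

        # independent oracle: per-slice point-in-circle membership
        oracle_vals = []
        zs = grid.z_levels
        ys = grid.origin[1] + np.arange(values.shape[1]) * grid.spacing[1]
        for c in sphere.contours:
            z = c[0, 2]
            k = int(np.argmin(np.abs(zs - z)))
            r = np.sqrt(45.0 ** 2 - z ** 2)
            for j, y in enumerate(ys):
                for i, x in enumerate(xs):
                    if x ** 2 + y ** 2 < r ** 2:
                        oracle_vals.append(values[k, j, i])
        oracle_mean = float(np.mean(oracle_vals))

        engine_vals = structure_dose_values(plan, sphere)
        assert engine_vals.mean() == pytest.approx(oracle_mean, abs=2.0)
        assert engine_vals.mean() == pytest.approx(50.0, abs=5.0)

    def test_no_dose_grid_is_not_applicable(self):
        results = check_dose_limits(build_plan(),
                                    build_rx(oar_limits=[OARLimit("OAR*", "MAX", 100)]))
        assert [r.status for r in results] == [CheckStatus.NOT_APPLICABLE]

    def test_unmatched_pattern_warns(self):
        plan = build_plan(dose_grid=uniform_dose_grid())
        rx = build_rx(oar_limits=[OARLimit("Cord*", "MAX", 100)])
        results = check_dose_limits(plan, rx)
        assert results[0].status is CheckStatus.WARN


class TestClearance:
    def test_compact_body_passes(self):
        assert check_clearance_proxy(build_plan()).status is CheckStatus.PASS

    def test_displaced_isocenter_warns_at_analytic_distance(self):
        # body ellipse semi-axis 150 mm; isocenter at x=-140 puts the distal
        # edge ~290 mm away laterally; with a 250 mm proxy radius this warns,
        # and the observed distance is bounded by the analytic worst case
        plan = build_plan(isocenter=(-140.0, 0, 0))
        r = check_clearance_proxy(plan, clearance_radius_mm=250.0)
        assert r.status is CheckStatus.WARN
        assert 250.0 < r.observed <= np.hypot(150.0 + 140.0, 100.0) + 1e-6

    def test_setup_only_plan_not_applicable(self):
        beams = [Beam("Setup", "6X", 0.0, 0, 0.0, is_setup_field=True)]
        r = check_clearance_proxy(build_plan(beams=beams))
        assert r.status is CheckStatus.NOT_APPLICABLE


class TestRunner:
    def test_clean_synthetic_plan_all_pass(self, clean_plan):
        plan, rx, _ = clean_plan
        report = run_checks(plan, rx)
        assert all(r.status is CheckStatus.PASS for r in report.results)

    def test_rerun_is_byte_identical(self, clean_plan):
        plan, rx, _ = clean_plan
        a = run_checks(plan, rx).to_json()
        b = run_checks(plan, rx).to_json()
        assert a == b

    def test_checks_do_not_mutate_plan(self, clean_plan):
        plan, rx, _ = clean_plan
        before = plan.content_fingerprint()
        run_checks(plan, rx)
        assert plan.content_fingerprint() == before

    def test_plan_without_dose_grid_only_dose_checks_na(self, clean_fileset):
        from planlint.plan_model import load_directive, load_plan

        fileset, _, _ = clean_fileset
        plan = load_plan(fileset.rtplan, fileset.rtstruct)  # no dose file
        rx = load_directive(fileset.directive)
        report = run_checks(plan, rx)
        by_id = report.by_id()
        assert by_id["dose_limits"][0].status is CheckStatus.NOT_APPLICABLE
        for cid, results in by_id.items():
            if cid != "dose_limits":
                assert all(r.status is CheckStatus.PASS for r in results), cid

    def test_raising_check_recorded_as_engine_error(self, clean_plan):
        plan, rx, _ = clean_plan

        def boom(p, r, k):
            raise RuntimeError("synthetic explosion")

        registry = CheckRegistry([
            CheckItem("exploding", CheckCategory.GEOMETRY, 5.0, boom)])
        report = run_checks(plan, rx, registry=registry)
        assert report.results[0].status is CheckStatus.FAIL
        assert "engine error" in report.results[0].message

    def test_registry_order_severity_descending(self):
        reg = default_registry()
        sev = [it.severity for it in reg]
        assert sev == sorted(sev, reverse=True)

    def test_fingerprint_changes_with_params(self):
        a = default_registry()
        b = default_registry()
        b.get("mu_sanity").params["high"] = 6.0
        assert a.fingerprint() != b.fingerprint()

    def test_non_pass_result_requires_message(self):
        with pytest.raises(ValueError):
            CheckResult("x", CheckStatus.FAIL, "")

    def test_report_json_round_trip(self, clean_plan):
        plan, rx, _ = clean_plan
        report = run_checks(plan, rx)
        again = CheckReport.from_json(report.to_json())
        assert again.to_json() == report.to_json()
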