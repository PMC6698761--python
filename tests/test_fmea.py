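"""FMEA scoring, Pareto ranking and phase comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from planlint.fmea import (
    FailureMode,
    compare_phases,
    compute_rpn,
    occurrence_score,
    pareto_rank,
    read_failure_modes,
    select_automation_candidates,
    severity_histogram,
    write_failure_modes,
)


def fm(item, s, o, d):
    return FailureMode(item=item, severity=s, occurrence=o, detectability=d)


class TestRPN:
    @pytest.mark.parametrize("s, o, d, expected", [
        (1, 1, 1, 1.0),
        (10, 10, 10, 1000.0),
        (9.3, 2, 5, 93.0),
    ])
    def test_product(self, s, o, d, expected):
        assert compute_rpn(fm("x", s, o, d)) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(0.5, 5, 5), (5, 11, 5), (5, 5, -1)])
    def test_out_of_range_scores_rejected(self, bad):
        with pytest.raises(ValueError):
            fm("x", *bad)

    def test_strictly_increasing_in_each_factor(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s, o, d = rng.uniform(1, 9.5, size=3)
            base = compute_rpn(fm("x", s, o, d))
            assert compute_rpn(fm("x", s + 0.5, o, d)) > base
            assert compute_rpn(fm("x", s, o + 0.5, d)) > base
            assert compute_rpn(fm("x", s, o, d + 0.5)) > base


class TestParetoRank:
    def _oracle_sort(self, items):
        """Independent insertion sort with explicit pairwise comparison."""
        out = []
        for x in items:
            i = 0
            while i < len(out):
                y = out[i]
                if (x.rpn, x.severity, [-ord(c) for c in x.item]) > \
                        (y.rpn, y.severity, [-ord(c) for c in y.item]):
                    break
                i += 1
            out.insert(i, x)
        return out

    def test_sorted_list_unchanged(self):
        items = [fm("a", 9, 9, 9), fm("b", 5, 5, 5), fm("c", 2, 2, 2)]
        assert pareto_rank(items) == items

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for trial in range(100):
            n = int(rng.integers(2, 30))
            items = [fm(f"item{i:02d}", *np.round(rng.uniform(1, 10, 3), 1))
                     for i in range(n)]
            rng.shuffle(items)
            assert pareto_rank(items) == self._oracle_sort(items)

    def test_tie_broken_by_severity(self):
        a = fm("a", 9.0, 2.0, 5.0)    # rpn 90
        b = fm("b", 5.0, 6.0, 3.0)    # rpn 90
        assert pareto_rank([b, a]) == [a, b]

    def test_idempotent_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        items = [fm(f"i{i}", *np.round(rng.uniform(1, 10, 3), 1)) for i in range(20)]
        ranked = pareto_rank(items)
        assert pareto_rank(ranked) == ranked
        shuffled = list(items)
        rng.shuffle(shuffled)
        assert pareto_rank(shuffled) == ranked


class TestCandidates:
    def test_high_severity_low_rpn_selected(self):
        # severity 7.3 with low O and D: selected on severity alone
        collision = fm("Plan: collision", 7.3, 1.5, 2.0)
        assert collision in select_automation_candidates([collision], rpn_cutoff=100)

    def test_severity_boundary_is_strict(self):
        borderline = fm("x", 7.0, 1.0, 1.0)
        assert select_automation_candidates([borderline], rpn_cutoff=100) == []

    def test_rpn_cutoff_inclusive(self):
        item = fm("x", 5.0, 5.0, 4.0)    # rpn 100
        assert item in select_automation_candidates([item], rpn_cutoff=100)

    def test_empty_input(self):
        assert select_automation_candidates([], rpn_cutoff=1) == []


class TestComparePhases:
    def test_identical_phases_zero_diff(self):
        items = [fm(f"i{i}", 5, 5, 5) for i in range(4)]
        cmp = compare_phases(items, items)
        assert cmp.mean_diff == 0.0
        assert all(d == 0.0 for d in cmp.delta_rpn)
        assert cmp.degenerate and math.isnan(cmp.p_value)

    def test_constant_shift_is_degenerate(self):
        # identical S*O with D shifted uniformly: every RPN drops by 40
        pre = [fm("a", 5, 4, 5), fm("b", 5, 4, 5), fm("c", 5, 4, 5)]
        post = [fm("a", 5, 4, 3), fm("b", 5, 4, 3), fm("c", 5, 4, 3)]
        cmp = compare_phases(pre, post)
        assert cmp.mean_diff == pytest.approx(-40.0)
        assert cmp.degenerate and math.isnan(cmp.p_value)

    def test_n3_matches_hand_computed_t(self):
        """Paired t on three items against the closed-form statistic."""
        pre = [fm("a", 8, 5, 6), fm("b", 7, 4, 5), fm("c", 9, 6, 4)]
        post = [fm("a", 8, 3, 4), fm("b", 7, 4, 4), fm("c", 9, 2, 3)]
        cmp = compare_phases(pre, post)
        diffs = np.array([post_fm.rpn - pre_fm.rpn
                          for pre_fm, post_fm in zip(pre, post)])
        mean = diffs.mean()
        sd = diffs.std(ddof=1)
        t_hand = mean / (sd / np.sqrt(3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=2)
        assert cmp.t_statistic == pytest.approx(t_hand, abs=1e-12)
        assert cmp.p_value == pytest.approx(p_hand, abs=1e-12)
        # cross-check against scipy's paired test as a second, library oracle
        t_sp, p_sp = stats.ttest_rel([f.rpn for f in post], [f.rpn for f in pre])
        assert cmp.t_statistic == pytest.approx(t_sp, abs=1e-9)
        assert cmp.p_value == pytest.approx(p_sp, abs=1e-9)

    def test_pairing_is_by_name_not_order(self):
        pre = [fm("a", 5, 5, 5), fm("b", 9, 9, 9)]
        post = [fm("b", 9, 9, 8), fm("a", 5, 5, 4)]
        cmp = compare_phases(pre, post)
        assert dict(zip(cmp.items, cmp.delta_rpn))["a"] == pytest.approx(-25.0)

    def test_mismatched_items_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            compare_phases([fm("a", 5, 5, 5), fm("b", 5, 5, 5)],
                           [fm("a", 5, 5, 5), fm("c", 5, 5, 5)])

    def test_mean_diff_identity(self):
        rng = np.random.default_rng(8)
        pre = [fm(f"i{i}", *np.round(rng.uniform(1, 10, 3), 1)) for i in range(10)]
        post = [fm(f"i{i}", *np.round(rng.uniform(1, 10, 3), 1)) for i in range(10)]
        cmp = compare_phases(pre, post)
        assert cmp.mean_diff == pytest.approx(cmp.mean_post - cmp.mean_pre,
                                              abs=1e-9)


class TestHistogram:
    def test_empty_all_zero(self):
        h = severity_histogram([])
        assert (h == 0).all()

    def test_single_error_normalized(self):
        h = severity_histogram([(8.0, 1)], normalize=True)
        assert h[8] == pytest.approx(1.0)
        assert h.sum() == pytest.approx(1.0)

    def test_mixed_severities_sum_to_one(self):
        h = severity_histogram([(8.4, 3), (7.1, 2), (2.0, 5)], normalize=True)
        assert h.sum() == pytest.approx(1.0, abs=1e-9)
        assert h[8] == pytest.approx(3 / 10)
        assert h[7] == pytest.approx(2 / 10)
        assert h[2] == pytest.approx(5 / 10)


class TestOccurrence:
    def test_zero_count_floor(self):
        assert occurrence_score(0, 1000) == 1.0

    def test_monotone_in_rate(self):
        scores = [occurrence_score(n, 1000) for n in (1, 5, 20, 100, 400, 900)]
        assert scores == sorted(scores)
        assert all(1 <= s <= 10 for s in scores)


class TestCSV:
    def test_round_trip(self, tmp_path):
        items = [fm("Rx v plan: site", 9.3, 2.0, 5.0), fm("Plan: MU", 7.9, 3.0, 4.0)]
        p = tmp_path / "fm.csv"
        write_failure_modes(items, p)
        again = read_failure_modes(p)
        assert again == items
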