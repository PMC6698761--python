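"""Failure mode and effects analysis (FMEA) for plan-check items.

Each plan-check step is scored on the TG-100 1–10 scales for Severity (S,
impact on the patient if the error is not caught), Occurrence (O, how often
the failure arises) and Detectability/Dormancy (D, probability the error
goes undetected).  The risk priority number RPN = S·O·D Pareto-ranks the
failure modes; the highest-RPN items and all items with severity above a
cutoff are the natural candidates for automation.  Committee scores are
averages and may be fractional (e.g. a severity of 9.3).

Re-scoring the same items after a process change and running a paired
t-test on the per-item RPNs quantifies whether the change moved the risk
profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FailureMode",
    "PhaseComparison",
    "compute_rpn",
    "pareto_rank",
    "select_automation_candidates",
    "compare_phases",
    "severity_histogram",
    "occurrence_score",
    "read_failure_modes",
    "write_failure_modes",
]


def _validate_score(name: str, value: float) -> float:
    value = float(value)
    if not (1.0 <= value <= 10.0):
        raise ValueError(f"{name} score {value} outside the TG-100 scale [1, 10]")
    return value


@dataclass(frozen=True)
class FailureMode:
    item: str
    severity: float
    occurrence: float
    detectability: float

    def __post_init__(self):
        _validate_score("severity", self.severity)
        _validate_score("occurrence", self.occurrence)
        _validate_score("detectability", self.detectability)

    @property
    def rpn(self) -> float:
        return compute_rpn(self)


def compute_rpn(fm: FailureMode) -> float:
    """RPN = S · O · D (each validated to [1, 10], so RPN ∈ [1, 1000])."""
    return fm.severity * fm.occurrence * fm.detectability


def pareto_rank(items: Sequence[FailureMode]) -> list[FailureMode]:
    """Sort failure modes by decreasing RPN.

    Ties break by severity descending, then item name ascending; the sort is
    stable, so the ordering is a pure function of the scores and names.
    """
    return sorted(items, key=lambda fm: (-fm.rpn, -fm.severity, fm.item))


def select_automation_candidates(items: Sequence[FailureMode],
                                 rpn_cutoff: float,
                                 severity_cutoff: float = 7.0) -> list[FailureMode]:
    """Items worth automating: RPN ≥ rpn_cutoff OR severity strictly > severity_cutoff.

    The union keeps low-frequency but catastrophic items (high S, low O) on
    the list even when their RPN is unremarkable.  Returned Pareto-ranked.
    """
    selected = [fm for fm in items
                if fm.rpn >= rpn_cutoff or fm.severity > severity_cutoff]
    return pareto_rank(selected)


@dataclass(frozen=True)
class PhaseComparison:
    items: tuple[str, ...]
    delta_rpn: tuple[float, ...]     # post − pre, per item
    mean_pre: float
    mean_post: float
    mean_diff: float                 # mean_post − mean_pre
    t_statistic: float
    p_value: float                   # two-sided paired t; NaN when degenerate
    degenerate: bool                 # all differences identical (zero variance)
    n: int


def compare_phases(pre: Sequence[FailureMode],
                   post: Sequence[FailureMode]) -> PhaseComparison:
    """Paired comparison of per-item RPNs between two scoring phases.

    Items are paired by name (order-independent); lists must contain the
    same items.  The two-sided paired t-test is computed from the mean and
    standard deviation of the per-item differences.  When every difference
    is identical the t statistic is undefined (zero variance); we return
    ``p_value = NaN`` with ``degenerate=True`` rather than a fake 0.
    """
    pre_by = {fm.item: fm for fm in pre}
    post_by = {fm.item: fm for fm in post}
    if len(pre_by) != len(pre) or len(post_by) != len(post):
        raise ValueError("duplicate item names within a phase")
    if set(pre_by) != set(post_by):
        missing = set(pre_by) ^ set(post_by)
        raise ValueError(f"phases are not paired; unmatched items: {sorted(missing)}")
    if len(pre_by) < 2:
        raise ValueError("paired comparison needs at least two items")

    items = tuple(sorted(pre_by))
    rpn_pre = np.array([pre_by[i].rpn for i in items])
    rpn_post = np.array([post_by[i].rpn for i in items])
    diffs = rpn_post - rpn_pre
    n = len(items)
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        t_stat, p, degenerate = math.nan, math.nan, True
        if mean_diff == 0.0:
            # identical phases: no effect, certain — still undefined t
            pass
    else:
        t_stat = mean_diff / (sd / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 1))
        degenerate = False
    return PhaseComparison(
        items=items,
        delta_rpn=tuple(float(d) for d in diffs),
        mean_pre=float(rpn_pre.mean()),
        mean_post=float(rpn_post.mean()),
        mean_diff=mean_diff,
        t_statistic=t_stat,
        p_value=p,
        degenerate=degenerate,
        n=n,
    )


def severity_histogram(errors: Sequence[tuple[float, int]],
                       normalize: bool = False) -> pd.Series:
    """Bin reported errors into integer severity bins 1–10.

    ``errors`` is a list of (severity score, error count) pairs; fractional
    committee scores land in the nearest integer bin.  With ``normalize``
    the frequencies sum to 1 (all-zero when there are no errors).
    """
    bins = pd.Series(0.0, index=pd.RangeIndex(1, 11, name="severity"))
    for severity, count in errors:
        b = int(np.clip(np.rint(severity), 1, 10))
        bins[b] += count
    if normalize:
        total = bins.sum()
        if total > 0:
            bins = bins / total
    return bins


#: log10-frequency mapping from incident-report rates to the TG-100 O scale.
#: Rates are events per plan; each decade of frequency spans ~3 score points.
_OCCURRENCE_TABLE = [
    (1e-4, 1.0), (3e-4, 2.0), (1e-3, 3.0), (3e-3, 4.0), (1e-2, 5.0),
    (3e-2, 6.0), (1e-1, 7.0), (2e-1, 8.0), (3.5e-1, 9.0),
]


def occurrence_score(event_count: int, n_plans: int) -> float:
    """Map an incident-learning-system count to a TG-100 occurrence score.

    The scale is logarithmic in the per-plan event rate; counts of zero map
    to the floor score 1.
    """
    if n_plans <= 0:
        raise ValueError("n_plans must be positive")
    if event_count < 0:
        raise ValueError("event_count must be non-negative")
    if event_count == 0:
        return 1.0
    rate = event_count / n_plans
    score = 10.0
    for threshold, s in _OCCURRENCE_TABLE:
        if rate <= threshold:
            score = s
            break
    return score


# ---------------------------------------------------------------------------
# CSV interchange (columns: item, S, O, D [, phase])
# ---------------------------------------------------------------------------

def read_failure_modes(path, phase: Optional[str] = None) -> list[FailureMode]:
    df = pd.read_csv(path)
    if phase is not None and "phase" in df.columns:
        df = df[df["phase"] == phase]
    return [FailureMode(item=str(r["item"]), severity=float(r["S"]),
                        occurrence=float(r["O"]), detectability=float(r["D"]))
            for _, r in df.iterrows()]


def write_failure_modes(items: Sequence[FailureMode], path) -> None:
    pd.DataFrame(
        [{"item": fm.item, "S": fm.severity, "O": fm.occurrence,
          "D": fm.detectability, "RPN": fm.rpn} for fm in items]
    ).to_csv(path, index=False)
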