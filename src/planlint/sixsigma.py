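"""Six Sigma defect arithmetic for process-quality monitoring.

Defects per opportunity (DPO) summarizes how often a countable error class
occurs given how many chances it had:

    DPO = errors / (opportunities_per_plan × n_plans)

The sigma level places that defect rate on the normal scale under the
conventional 1.5σ long-term shift:

    sigma_level(DPO) = Φ⁻¹(1 − DPO) + 1.5

so that a "six sigma" process corresponds to DPO ≈ 3.4 × 10⁻⁶ and a 5σ
process to a yield of 99.977%.  The integer sigma *class* is the floor of
the level (a process at level 4.6 is still "within 4σ").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "DefectSummary",
    "SigmaAssessment",
    "compute_dpo",
    "sigma_level",
    "sigma_class",
    "dpo_for_sigma",
    "yield_for_sigma",
    "assess",
    "relative_error_reduction",
    "SIX_SIGMA_DPO_GOAL",
]

#: the conventional Six Sigma goal, DPO at sigma level 6 (≈ 3.4 per million)
SIX_SIGMA_DPO_GOAL = float(norm.sf(6.0 - 1.5))


@dataclass(frozen=True)
class DefectSummary:
    errors: int
    opportunities_per_plan: int
    n_plans: int

    @property
    def dpo(self) -> float:
        return compute_dpo(self.errors, self.opportunities_per_plan, self.n_plans)


@dataclass(frozen=True)
class SigmaAssessment:
    dpo: float
    sigma_level: float
    sigma_class: int
    process_yield: float     # 1 − DPO at the computed level


def compute_dpo(errors: int, opportunities_per_plan: int, n_plans: int) -> float:
    """Exact defects-per-opportunity ratio with bound validation."""
    if errors < 0 or opportunities_per_plan < 0 or n_plans < 0:
        raise ValueError("counts must be non-negative")
    total_opportunities = opportunities_per_plan * n_plans
    if total_opportunities <= 0:
        raise ValueError("total opportunities must be positive")
    if errors > total_opportunities:
        raise ValueError(
            f"errors ({errors}) exceed total opportunities ({total_opportunities})")
    return errors / total_opportunities


def sigma_level(dpo: float) -> float:
    """Sigma level Φ⁻¹(1 − DPO) + 1.5 for DPO strictly inside (0, 1)."""
    if not (0.0 < dpo < 1.0):
        raise ValueError(
            f"sigma level undefined for dpo={dpo}: a defect rate of exactly 0 "
            f"or 1 maps to an infinite/degenerate level")
    return float(norm.isf(dpo)) + 1.5


def sigma_class(dpo: float) -> int:
    """Integer sigma class: floor of the sigma level.

    Floor, not nearest — a process with level 4.64 has not reached 5σ
    performance; it is classed "within 4σ".
    """
    return math.floor(sigma_level(dpo))


def dpo_for_sigma(sigma: float) -> float:
    """Defect rate at a given sigma level (exact inverse of sigma_level)."""
    return float(norm.sf(sigma - 1.5))


def yield_for_sigma(sigma: float) -> float:
    """Process yield 1 − DPO at a given sigma level."""
    return 1.0 - dpo_for_sigma(sigma)


def assess(errors: int, opportunities_per_plan: int, n_plans: int) -> SigmaAssessment:
    dpo = compute_dpo(errors, opportunities_per_plan, n_plans)
    level = sigma_level(dpo)
    return SigmaAssessment(dpo=dpo, sigma_level=level,
                           sigma_class=math.floor(level),
                           process_yield=1.0 - dpo)


def relative_error_reduction(errors_before: int, n_before: int,
                             errors_after: int, n_after: int) -> float:
    """Relative decrease in per-plan error rate between two arms.

    Returns (rate_before − rate_after) / rate_before, e.g. 5 errors in 10
    plans versus 1 error in 10 plans gives 0.80 (an 80% reduction).
    """
    if n_before <= 0 or n_after <= 0:
        raise ValueError("plan counts must be positive")
    rate_before = errors_before / n_before
    rate_after = errors_after / n_after
    if rate_before == 0:
        raise ValueError("relative reduction undefined when the baseline rate is 0")
    return (rate_before - rate_after) / rate_before
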