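"""Deterministic expected-value cost engine.

Partitions the annual cohort into expected true/false positive/negative
counts under a strategy's effective operating point and prices the three
cost components:

* testing — every patient pays for the tests on their path;
* immunotherapy — true positives receive a full pembrolizumab course,
  false positives discontinue at the first restaging scan (3 doses);
* chemotherapy — true negatives receive the share-weighted 5-FU-based mix
  for its weighted median duration; whether false negatives also accrue
  chemotherapy cost is governed by ``ChemoParams.fn_cost_policy``.

Expected counts are fractional patients; currency is carried at full
precision and only the reported total is rounded (component-wise, to
billions at 2 dp half-up — the convention under which the published
component cells sum to the published totals).
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ChemoParams, FnCostPolicy, FpDosePriceBasis, ModelConfig, PembroParams
from .rounding import round_half_up, usd_to_billions
from .strategies import (
    EffectiveCharacteristics,
    Strategy,
    effective_characteristics,
    expected_testing_cost_per_patient,
)

__all__ = [
    "CohortPartition",
    "CostBreakdown",
    "partition_cohort",
    "immunotherapy_cost",
    "chemotherapy_cost",
    "testing_cost_total",
    "fp_cost_per_patient",
    "evaluate_costs",
]


@dataclass(frozen=True)
class CohortPartition:
    """Expected confusion-matrix patient counts (fractional)."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CostBreakdown:
    """Cohort-level costs in USD; ``total_reported`` in billions at 2 dp.

    ``total_unrounded`` is the exact component sum; ``total_reported`` sums
    the three components after each is rounded to billions at 2 dp half-up.
    """

    testing: float
    immunotherapy: float
    chemotherapy: float
    total_unrounded: float
    total_reported: float

    @classmethod
    def from_components(
        cls, testing: float, immunotherapy: float, chemotherapy: float
    ) -> "CostBreakdown":
        return cls(
            testing=testing,
            immunotherapy=immunotherapy,
            chemotherapy=chemotherapy,
            total_unrounded=testing + immunotherapy + chemotherapy,
            total_reported=round_half_up(
                usd_to_billions(testing)
                + usd_to_billions(immunotherapy)
                + usd_to_billions(chemotherapy),
                2,
            ),
        )


def partition_cohort(
    N: float, prevalence: float, ec: EffectiveCharacteristics
) -> CohortPartition:
    """Expected TP/FP/FN/TN counts for ``N`` patients at the given prevalence."""
    if N <= 0:
        raise ValueError(f"cohort size must be > 0, got {N!r}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence out of [0, 1]: {prevalence!r}")
    diseased = N * prevalence
    healthy = N - diseased
    return CohortPartition(
        tp=diseased * ec.sensitivity,
        fn=diseased * (1.0 - ec.sensitivity),
        fp=healthy * (1.0 - ec.specificity),
        tn=healthy * ec.specificity,
    )


def fp_cost_per_patient(p: PembroParams) -> float:
    """Pembrolizumab cost of one false positive (stops at first restaging)."""
    if p.fp_dose_price_basis is FpDosePriceBasis.monthly_rate_per_dose:
        return p.fp_discontinuation_doses * p.monthly_cost
    return p.fp_discontinuation_doses * p.dose_interval_months * p.monthly_cost


def immunotherapy_cost(part: CohortPartition, p: PembroParams) -> float:
    """Full course for true positives plus the discontinuation cost of false positives."""
    return part.tp * p.monthly_cost * p.full_course_months + part.fp * fp_cost_per_patient(p)


def chemotherapy_cost(part: CohortPartition, c: ChemoParams) -> float:
    """Weighted monthly cost x weighted median duration for the chemo-treated count."""
    n = part.tn if c.fn_cost_policy is FnCostPolicy.tn_only else part.tn + part.fn
    return n * c.weighted_monthly_cost * c.weighted_median_months


def testing_cost_total(N: float, s: Strategy, prevalence: float) -> float:
    """Cohort testing cost: N x expected per-patient testing cost."""
    if N < 0:
        raise ValueError(f"cohort size must be >= 0, got {N!r}")
    return N * expected_testing_cost_per_patient(s, prevalence)


def evaluate_costs(s: Strategy, config: ModelConfig) -> CostBreakdown:
    """Full cost breakdown of one strategy under a model configuration."""
    N = config.cohort_size
    prev = config.population.msih_prevalence
    part = partition_cohort(N, prev, effective_characteristics(s))
    return CostBreakdown.from_components(
        testing=testing_cost_total(N, s, prev),
        immunotherapy=immunotherapy_cost(part, config.pembro),
        chemotherapy=chemotherapy_cost(part, config.chemo),
    )
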