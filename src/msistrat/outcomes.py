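"""Clinical-impact metrics per testing strategy.

Three cohort-level metrics summarise the clinical consequences of a
strategy: the branch-weighted mean time to treatment initiation (summed
test turnarounds on each path), the percentage of patients whose results
arrive within the guideline-recommended window, and the percentage whose
final first-line therapy is concordant with their true MMR/MSI status
(pembrolizumab for dMMR/MSI-H, chemotherapy for pMMR/MSS) — i.e. therapy
supported by the pivotal first-line trial evidence.

Concordance is evaluated on the final treatment assignment, after every
test on the patient's path has resulted (no treat-while-confirming).
"""

from __future__ import annotations

from dataclasses import dataclass

from .costs import CohortPartition, partition_cohort
from .params import GuidelineParams, ModelConfig
from .rounding import round_half_up
from .strategies import Strategy, effective_characteristics, enumerate_branches

__all__ = [
    "ClinicalOutcomes",
    "time_to_treatment",
    "pct_within_guideline",
    "supported_therapy",
    "evaluate_outcomes",
]


@dataclass(frozen=True)
class ClinicalOutcomes:
    """Cohort-level clinical impact of a testing strategy."""

    mean_days_to_treatment: float
    pct_within_guideline: float
    pct_supported: float
    supported_count: int

    def __post_init__(self) -> None:
        if self.mean_days_to_treatment < 0:
            raise ValueError("mean_days_to_treatment must be >= 0")
        for name in ("pct_within_guideline", "pct_supported"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v!r}")


def time_to_treatment(s: Strategy, prevalence: float) -> float:
    """Branch-weighted mean days from sample receipt to treatment initiation."""
    return sum(
        b.population_fraction * b.days_to_result
        for b in enumerate_branches(s, prevalence)
    )


def pct_within_guideline(
    s: Strategy, prevalence: float, g: GuidelineParams
) -> float:
    """Percent of patients whose full testing path resolves within the window."""
    return 100.0 * sum(
        b.population_fraction
        for b in enumerate_branches(s, prevalence)
        if b.days_to_result <= g.max_working_days
    )


def supported_therapy(part: CohortPartition) -> tuple[int, float]:
    """(count, percent) of patients whose final therapy matches their true status.

    The count (TP + TN expected patients) is rounded half-up for display;
    the percentage is exact.
    """
    supported = part.tp + part.tn
    return int(round_half_up(supported)), 100.0 * supported / part.total


def evaluate_outcomes(s: Strategy, config: ModelConfig) -> ClinicalOutcomes:
    """All three clinical metrics for one strategy under a configuration."""
    prev = config.population.msih_prevalence
    part = partition_cohort(config.cohort_size, prev, effective_characteristics(s))
    count, pct = supported_therapy(part)
    return ClinicalOutcomes(
        mean_days_to_treatment=time_to_treatment(s, prev),
        pct_within_guideline=pct_within_guideline(s, prev, config.guideline),
        pct_supported=pct,
        supported_count=count,
    )
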