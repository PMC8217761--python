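"""Testing-strategy algebra: screen/confirm composition over decision trees.

A strategy is a single assay or a two-stage plan in which one arm of the
screening result (positives or negatives) is re-tested by a confirmatory
assay before the final MMR/MSI call. Serial-testing algebra gives the
effective operating point of the composed plan:

* confirm on positives (final positive requires both tests positive):
  ``se = se1*se2``, ``sp = 1 - (1-sp1)*(1-sp2)``
* confirm on negatives (final positive if either test is positive):
  ``se = se1 + (1-se1)*se2``, ``sp = sp1*sp2``

Treatment starts only after every test on a patient's path has resulted, so
a branch's days-to-result is the sum of the turnarounds on that path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .params import Assay, ConfigError, ModelConfig

__all__ = [
    "ConfirmArm",
    "Strategy",
    "EffectiveCharacteristics",
    "Branch",
    "builtin_strategies",
    "BUILTIN_STRATEGY_NAMES",
    "effective_characteristics",
    "enumerate_branches",
    "expected_testing_cost_per_patient",
]

_FRACTION_TOL = 1e-9


class ConfirmArm(str, Enum):
    none = "none"
    positives = "positives"
    negatives = "negatives"


@dataclass(frozen=True)
class Strategy:
    """A single- or two-stage MMR/MSI testing plan."""

    name: str
    screen: Assay
    confirm: Assay | None = None
    confirm_arm: ConfirmArm = ConfirmArm.none
    slug: str = ""

    def __post_init__(self) -> None:
        if (self.confirm is None) != (self.confirm_arm is ConfirmArm.none):
            raise ValueError(
                "confirm_arm must be 'none' exactly when no confirm assay is given"
            )

    @property
    def assays(self) -> tuple[Assay, ...]:
        return (self.screen,) if self.confirm is None else (self.screen, self.confirm)


@dataclass(frozen=True)
class EffectiveCharacteristics:
    """Sensitivity/specificity of the composed final call."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"characteristic out of [0, 1]: {v!r}")


@dataclass(frozen=True)
class Branch:
    """One observable path through a strategy's decision tree."""

    label: str
    population_fraction: float
    tests_applied: tuple[str, ...]
    days_to_result: float
    final_call: str  # "positive" | "negative"
    testing_cost: float = field(default=0.0)


BUILTIN_STRATEGY_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H")


def builtin_strategies(config: ModelConfig) -> list[Strategy]:
    """The eight built-in strategies, named A-H.

    A: NGS alone; B: high-sensitivity panel alone; C: high-specificity panel
    alone; D: high-specificity AI alone; E: high-sensitivity AI with NGS
    confirmation of AI-positives; F: high-specificity AI with NGS
    confirmation of AI-negatives; G: high-sensitivity AI with high-sensitivity
    panel confirmation of AI-positives; H: high-sensitivity AI with
    high-specificity panel confirmation of AI-positives.
    """
    a = config.assay
    return [
        Strategy("A", a("ngs"), slug="ngs-only"),
        Strategy("B", a("panel_high_sens"), slug="high-sens-panel-only"),
        Strategy("C", a("panel_high_spec"), slug="high-spec-panel-only"),
        Strategy("D", a("ai_high_spec"), slug="high-spec-ai-only"),
        Strategy(
            "E", a("ai_high_sens"), a("ngs"), ConfirmArm.positives,
            slug="high-sens-ai-confirm-ngs-positives",
        ),
        Strategy(
            "F", a("ai_high_spec"), a("ngs"), ConfirmArm.negatives,
            slug="high-spec-ai-confirm-ngs-negatives",
        ),
        Strategy(
            "G", a("ai_high_sens"), a("panel_high_sens"), ConfirmArm.positives,
            slug="high-sens-ai-confirm-high-sens-panel-positives",
        ),
        Strategy(
            "H", a("ai_high_sens"), a("panel_high_spec"), ConfirmArm.positives,
            slug="high-sens-ai-confirm-high-spec-panel-positives",
        ),
    ]


def effective_characteristics(s: Strategy) -> EffectiveCharacteristics:
    """Operating point of the strategy's final call (serial-testing algebra)."""
    se1, sp1 = s.screen.sensitivity, s.screen.specificity
    if s.confirm is None:
        return EffectiveCharacteristics(se1, sp1)
    se2, sp2 = s.confirm.sensitivity, s.confirm.specificity
    if s.confirm_arm is ConfirmArm.positives:
        return EffectiveCharacteristics(se1 * se2, 1.0 - (1.0 - sp1) * (1.0 - sp2))
    return EffectiveCharacteristics(se1 + (1.0 - se1) * se2, sp1 * sp2)


def _screen_positive_fraction(s: Strategy, prevalence: float) -> float:
    se1, sp1 = s.screen.sensitivity, s.screen.specificity
    return prevalence * se1 + (1.0 - prevalence) * (1.0 - sp1)


def enumerate_branches(s: Strategy, prevalence: float) -> list[Branch]:
    """Observable decision-tree paths with population fractions by total probability.

    Zero-probability paths are dropped; surviving fractions sum to 1.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence out of [0, 1]: {prevalence!r}")
    se1, sp1 = s.screen.sensitivity, s.screen.specificity
    t1, c1 = s.screen.turnaround_days, s.screen.cost_per_patient
    q = 1.0 - prevalence
    p_pos = _screen_positive_fraction(s, prevalence)
    p_neg = 1.0 - p_pos

    branches: list[Branch] = []
    if s.confirm is None:
        branches = [
            Branch("screen_pos_final_pos", p_pos, (s.screen.name,), t1, "positive", c1),
            Branch("screen_neg_final_neg", p_neg, (s.screen.name,), t1, "negative", c1),
        ]
    else:
        se2, sp2 = s.confirm.sensitivity, s.confirm.specificity
        t2, c2 = s.confirm.turnaround_days, s.confirm.cost_per_patient
        tests = (s.screen.name, s.confirm.name)
        if s.confirm_arm is ConfirmArm.positives:
            # screen-positives are re-tested; screen-negatives are final negative
            pp = prevalence * se1 * se2 + q * (1.0 - sp1) * (1.0 - sp2)
            pn = prevalence * se1 * (1.0 - se2) + q * (1.0 - sp1) * sp2
            branches = [
                Branch("screen_pos_final_pos", pp, tests, t1 + t2, "positive", c1 + c2),
                Branch("screen_pos_final_neg", pn, tests, t1 + t2, "negative", c1 + c2),
                Branch(
                    "screen_neg_final_neg", p_neg, (s.screen.name,), t1, "negative", c1
                ),
            ]
        else:
            # screen-negatives are re-tested; screen-positives are final positive
            np_ = prevalence * (1.0 - se1) * se2 + q * sp1 * (1.0 - sp2)
            nn = prevalence * (1.0 - se1) * (1.0 - se2) + q * sp1 * sp2
            branches = [
                Branch(
                    "screen_pos_final_pos", p_pos, (s.screen.name,), t1, "positive", c1
                ),
                Branch("screen_neg_final_pos", np_, tests, t1 + t2, "positive", c1 + c2),
                Branch("screen_neg_final_neg", nn, tests, t1 + t2, "negative", c1 + c2),
            ]
    branches = [b for b in branches if b.population_fraction > 0.0]
    total = sum(b.population_fraction for b in branches)
    assert abs(total - 1.0) <= 1e-9, f"branch fractions sum to {total}"
    return branches


def expected_testing_cost_per_patient(s: Strategy, prevalence: float) -> float:
    """Screen cost plus the confirm cost weighted by the re-tested fraction."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence out of [0, 1]: {prevalence!r}")
    cost = s.screen.cost_per_patient
    if s.confirm is not None:
        p_pos = _screen_positive_fraction(s, prevalence)
        frac = p_pos if s.confirm_arm is ConfirmArm.positives else 1.0 - p_pos
        cost += frac * s.confirm.cost_per_patient
    return cost
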