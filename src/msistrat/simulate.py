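"""Patient-level Monte Carlo microsimulation and probabilistic sensitivity analysis.

The deterministic engine computes expected values in closed form; this
module provides two stochastic counterparts:

* :func:`simulate_cohort` — a brute-force patient-level simulator that draws
  Bernoulli disease status and per-test Bernoulli outcomes (independent
  errors given true status) and accumulates costs and outcomes under exactly
  the same accounting conventions as the deterministic engine. It serves as
  a verification oracle: aggregates scaled to the configured cohort size
  must agree with the closed-form values within Monte Carlo error.
* :func:`draw_psa_parameters` / :func:`run_psa` — probabilistic sensitivity
  analysis over random parameter sets (beta for proportions, gamma for
  costs, moment-matched around the base configuration), an extension beyond
  the deterministic point estimate.

All randomness flows through one seeded ``numpy`` generator; the per-stage
uniform draws are generated as whole arrays up front, so results do not
depend on patient iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costs import (
    CostBreakdown,
    evaluate_costs,
    fp_cost_per_patient,
)
from .params import FnCostPolicy, ModelConfig
from .outcomes import ClinicalOutcomes
from .rounding import round_half_up
from .strategies import ConfirmArm, Strategy

__all__ = [
    "SimulationResult",
    "PsaDistributionSpec",
    "PsaResult",
    "simulate_cohort",
    "draw_psa_parameters",
    "run_psa",
]

DMMR = "dMMR_MSI_H"
PMMR = "pMMR_MSS"


@dataclass(frozen=True)
class SimulationResult:
    """Patient records plus cohort-scaled aggregates and their Monte Carlo SEs."""

    patients: pd.DataFrame
    costs: CostBreakdown
    outcomes: ClinicalOutcomes
    standard_errors: dict[str, float]
    n: int
    scale: float  # cohort size / simulated n


def simulate_cohort(
    s: Strategy, config: ModelConfig, n: int, seed: int
) -> SimulationResult:
    """Simulate ``n`` patients through a strategy; aggregates scaled to the cohort.

    Disease status is Bernoulli(prevalence); each administered test's result
    is Bernoulli(sensitivity) for diseased and Bernoulli(1-specificity) for
    non-diseased patients, independent across tests. Costs follow the
    deterministic engine's conventions (full pembrolizumab course for true
    positives, discontinuation doses for false positives, weighted chemo
    course for true negatives, false negatives per ``fn_cost_policy``).
    Fully reproducible for a given seed.
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n!r}")
    prev = config.population.msih_prevalence
    rng = np.random.default_rng(seed)
    u_status, u_screen, u_confirm = rng.random((3, n))

    diseased = u_status < prev
    scr = s.screen
    screen_pos = np.where(
        diseased, u_screen < scr.sensitivity, u_screen < 1.0 - scr.specificity
    )

    days = np.full(n, float(scr.turnaround_days))
    testing = np.full(n, float(scr.cost_per_patient))
    confirm_pos = np.zeros(n, dtype=bool)
    in_confirm = np.zeros(n, dtype=bool)
    if s.confirm is not None:
        conf = s.confirm
        in_confirm = screen_pos if s.confirm_arm is ConfirmArm.positives else ~screen_pos
        confirm_pos = np.where(
            diseased, u_confirm < conf.sensitivity, u_confirm < 1.0 - conf.specificity
        )
        confirm_pos &= in_confirm
        days = days + in_confirm * float(conf.turnaround_days)
        testing = testing + in_confirm * float(conf.cost_per_patient)
        if s.confirm_arm is ConfirmArm.positives:
            final_pos = screen_pos & confirm_pos
        else:
            final_pos = screen_pos | confirm_pos
    else:
        final_pos = screen_pos

    tp = final_pos & diseased
    fp = final_pos & ~diseased
    tn = ~final_pos & ~diseased
    fn = ~final_pos & diseased

    p = config.pembro
    c = config.chemo
    immuno = tp * (p.monthly_cost * p.full_course_months) + fp * fp_cost_per_patient(p)
    chemo_pp = c.weighted_monthly_cost * c.weighted_median_months
    chemo_mask = tn if c.fn_cost_policy is FnCostPolicy.tn_only else tn | fn
    chemo = chemo_mask * chemo_pp
    therapy = immuno + chemo

    N = config.cohort_size
    scale = N / n
    costs = CostBreakdown.from_components(
        testing=float(testing.sum()) * scale,
        immunotherapy=float(immuno.sum()) * scale,
        chemotherapy=float(chemo.sum()) * scale,
    )

    within = days <= config.guideline.max_working_days
    supported = final_pos == diseased
    outcomes = ClinicalOutcomes(
        mean_days_to_treatment=float(days.mean()),
        pct_within_guideline=100.0 * float(within.mean()),
        pct_supported=100.0 * float(supported.mean()),
        supported_count=int(round_half_up(float(supported.mean()) * N)),
    )

    sqn = np.sqrt(n)
    standard_errors = {
        "testing": float(testing.std(ddof=1)) / sqn * N,
        "immunotherapy": float(immuno.std(ddof=1)) / sqn * N,
        "chemotherapy": float(chemo.std(ddof=1)) / sqn * N,
        "total": float((testing + therapy).std(ddof=1)) / sqn * N,
        "mean_days_to_treatment": float(days.std(ddof=1)) / sqn,
        "pct_within_guideline": 100.0 * _bernoulli_se(within.mean(), n),
        "pct_supported": 100.0 * _bernoulli_se(supported.mean(), n),
    }

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "true_status": np.where(diseased, DMMR, PMMR),
            "screen_result": np.where(screen_pos, "positive", "negative"),
            "confirm_result": np.where(
                in_confirm, np.where(confirm_pos, "positive", "negative"), ""
            ),
            "final_call": np.where(final_pos, "positive", "negative"),
            "days_to_treatment": days,
            "testing_cost": testing,
            "therapy_cost": therapy,
            "therapy_class": np.where(final_pos, "immunotherapy", "chemotherapy"),
        }
    )
    return SimulationResult(
        patients=patients,
        costs=costs,
        outcomes=outcomes,
        standard_errors=standard_errors,
        n=n,
        scale=scale,
    )


def _bernoulli_se(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1.0 - p), 0.0) / n))


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PsaDistributionSpec:
    """Parameter-uncertainty model for PSA draws around a base configuration.

    Proportions (prevalence, sensitivities, specificities) are drawn from
    moment-matched beta distributions with standard deviation
    ``proportion_rel_sd`` x mean; costs (per-test, pembrolizumab monthly,
    weighted chemo monthly) from gamma distributions with standard deviation
    ``cost_rel_sd`` x mean. A relative SD of 0 makes the draw degenerate at
    the base value. 10% relative SDs are conventional health-economics
    defaults, not published inputs.
    """

    base: ModelConfig
    proportion_rel_sd: float = 0.10
    cost_rel_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportion_rel_sd < 0 or self.cost_rel_sd < 0:
            raise ValueError("relative SDs must be >= 0")


def _draw_beta(rng: np.random.Generator, mean: float, rel_sd: float) -> float:
    if rel_sd == 0.0 or mean <= 0.0 or mean >= 1.0:
        return mean
    sd = min(rel_sd * mean, 0.99 * np.sqrt(mean * (1.0 - mean)))
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _draw_gamma(rng: np.random.Generator, mean: float, rel_sd: float) -> float:
    if rel_sd == 0.0 or mean <= 0.0:
        return mean
    shape = 1.0 / rel_sd**2
    return float(rng.gamma(shape, mean * rel_sd**2))


def draw_psa_parameters(spec: PsaDistributionSpec, n_draws: int) -> list[ModelConfig]:
    """``n_draws`` valid random configurations around the base; seed-reproducible."""
    if n_draws <= 0:
        raise ValueError(f"n_draws must be > 0, got {n_draws!r}")
    rng = np.random.default_rng(spec.seed)
    p_sd, c_sd = spec.proportion_rel_sd, spec.cost_rel_sd
    configs: list[ModelConfig] = []
    for _ in range(n_draws):
        raw = spec.base.model_dump()
        raw["population"]["msih_prevalence"] = _draw_beta(
            rng, spec.base.population.msih_prevalence, p_sd
        )
        for key in sorted(raw["assays"]):
            a = raw["assays"][key]
            a["sensitivity"] = _draw_beta(rng, a["sensitivity"], p_sd)
            a["specificity"] = _draw_beta(rng, a["specificity"], p_sd)
            a["cost_per_patient"] = _draw_gamma(rng, a["cost_per_patient"], c_sd)
        raw["pembro"]["monthly_cost"] = _draw_gamma(
            rng, spec.base.pembro.monthly_cost, c_sd
        )
        raw["chemo"]["weighted_monthly_cost"] = _draw_gamma(
            rng, spec.base.chemo.weighted_monthly_cost, c_sd
        )
        configs.append(ModelConfig.model_validate(raw))
    return configs


@dataclass(frozen=True)
class PsaResult:
    """Per-draw totals/savings and summary quantiles across PSA draws."""

    draws: pd.DataFrame  # columns: draw, strategy, total_usd, savings_usd
    summary: pd.DataFrame  # per strategy: savings quantiles 2.5/50/97.5%
    reference: str


def _rebind(s: Strategy, config: ModelConfig) -> Strategy:
    """Re-resolve a strategy's assays against another configuration's assay set."""
    by_name = {a.name: a for a in config.assays.values()}
    return Strategy(
        name=s.name,
        screen=by_name[s.screen.name],
        confirm=None if s.confirm is None else by_name[s.confirm.name],
        confirm_arm=s.confirm_arm,
        slug=s.slug,
    )


def run_psa(
    strategies: list[Strategy],
    configs: list[ModelConfig],
    reference: Strategy | str,
) -> PsaResult:
    """Evaluate every strategy under every drawn configuration.

    Savings are unrounded total cost of the reference minus the strategy,
    per draw; the summary reports the 2.5/50/97.5% quantiles per strategy.
    """
    if not strategies or not configs:
        raise ValueError("strategies and configs must be non-empty")
    ref_name = reference if isinstance(reference, str) else reference.name
    names = [s.name for s in strategies]
    if ref_name not in names:
        raise ValueError(f"reference {ref_name!r} not among strategies {names}")

    rows = []
    for i, cfg in enumerate(configs):
        totals = {
            s.name: evaluate_costs(_rebind(s, cfg), cfg).total_unrounded
            for s in strategies
        }
        ref_total = totals[ref_name]
        for name, total in totals.items():
            rows.append(
                {
                    "draw": i,
                    "strategy": name,
                    "total_usd": total,
                    "savings_usd": ref_total - total,
                }
            )
    draws = pd.DataFrame(rows)
    summary = (
        draws.groupby("strategy")["savings_usd"]
        .quantile([0.025, 0.5, 0.975])
        .unstack()
        .rename(columns={0.025: "q2.5", 0.5: "median", 0.975: "q97.5"})
        .reindex(names)
    )
    return PsaResult(draws=draws, summary=summary, reference=ref_name)
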