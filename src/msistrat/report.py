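"""Results assembly, savings vs a reference strategy, rendering, and
comparison against the bundled published-values fixture.

The results matrix is the package's analogue of the published
strategy-by-metric table: per-strategy cost breakdowns and clinical
outcomes, plus absolute and relative savings against a reference strategy
(NGS-alone by convention). Savings are computed on two bases and both are
stored: the unrounded component sums (the default headline basis) and the
sum of components rounded to billions at 2 dp (the display convention under
which the published component cells reproduce the published totals).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .costs import CostBreakdown, evaluate_costs
from .outcomes import ClinicalOutcomes, evaluate_outcomes
from .params import ModelConfig
from .rounding import round_half_up
from .strategies import Strategy, builtin_strategies

__all__ = [
    "StrategyResult",
    "SavingsRow",
    "ResultsMatrix",
    "build_results_matrix",
    "render",
    "paper_delta_report",
    "printed_reference_table",
]

_METRIC_ORDER = (
    "total",
    "chemotherapy",
    "immunotherapy",
    "testing",
    "ttt_days",
    "pct_within_guideline",
    "pct_supported",
)


@dataclass(frozen=True)
class StrategyResult:
    name: str
    slug: str
    costs: CostBreakdown
    outcomes: ClinicalOutcomes


@dataclass(frozen=True)
class SavingsRow:
    """Savings of one strategy vs the reference, on both rounding bases."""

    abs_unrounded_usd: float
    rel_pct_unrounded: float
    abs_rounded_busd: float
    rel_pct_rounded: float


@dataclass(frozen=True)
class ResultsMatrix:
    """Per-strategy results plus savings vs the reference strategy."""

    results: dict[str, StrategyResult]
    reference: str | None
    savings: dict[str, SavingsRow]

    @property
    def strategy_names(self) -> list[str]:
        return list(self.results)

    def to_frame(self) -> pd.DataFrame:
        """One row per strategy; full-precision numeric columns."""
        rows = []
        for name, r in self.results.items():
            sv = self.savings.get(name)
            rows.append(
                {
                    "strategy": name,
                    "slug": r.slug,
                    "testing_usd": r.costs.testing,
                    "immunotherapy_usd": r.costs.immunotherapy,
                    "chemotherapy_usd": r.costs.chemotherapy,
                    "total_unrounded_usd": r.costs.total_unrounded,
                    "total_reported_busd": r.costs.total_reported,
                    "mean_days_to_treatment": r.outcomes.mean_days_to_treatment,
                    "pct_within_guideline": r.outcomes.pct_within_guideline,
                    "pct_supported": r.outcomes.pct_supported,
                    "supported_count": r.outcomes.supported_count,
                    "savings_abs_unrounded_usd": sv.abs_unrounded_usd if sv else None,
                    "savings_rel_pct_unrounded": sv.rel_pct_unrounded if sv else None,
                    "savings_abs_rounded_busd": sv.abs_rounded_busd if sv else None,
                    "savings_rel_pct_rounded": sv.rel_pct_rounded if sv else None,
                }
            )
        return pd.DataFrame(rows)

    def displayed(self, name: str, metric: str) -> float:
        """A cell at display precision (billions 2 dp; days 1 dp; percents 0 dp)."""
        r = self.results[name]
        if metric in ("total",):
            return r.costs.total_reported
        if metric in ("chemotherapy", "immunotherapy", "testing"):
            return round_half_up(getattr(r.costs, metric) / 1e9, 2)
        if metric == "ttt_days":
            return round_half_up(r.outcomes.mean_days_to_treatment, 1)
        if metric == "pct_within_guideline":
            return round_half_up(r.outcomes.pct_within_guideline, 0)
        if metric == "pct_supported":
            return round_half_up(r.outcomes.pct_supported, 0)
        raise KeyError(f"unknown metric {metric!r}")


def build_results_matrix(
    config: ModelConfig,
    strategies: list[Strategy] | None = None,
    reference: str | None = "A",
) -> ResultsMatrix:
    """Evaluate every strategy and attach savings vs the reference.

    ``strategies`` defaults to the eight built-ins. ``reference`` must name
    one of the evaluated strategies (or be ``None`` for no savings rows,
    which is also permitted for an empty strategy list).
    """
    if strategies is None:
        strategies = builtin_strategies(config)
    names = [s.name for s in strategies]
    if reference is not None and reference not in names:
        raise ValueError(f"reference {reference!r} not among strategies {names}")

    results = {
        s.name: StrategyResult(
            name=s.name,
            slug=s.slug,
            costs=evaluate_costs(s, config),
            outcomes=evaluate_outcomes(s, config),
        )
        for s in strategies
    }
    savings: dict[str, SavingsRow] = {}
    if reference is not None:
        ref = results[reference].costs
        for name, r in results.items():
            abs_unrounded = ref.total_unrounded - r.costs.total_unrounded
            abs_rounded = round_half_up(ref.total_reported - r.costs.total_reported, 2)
            savings[name] = SavingsRow(
                abs_unrounded_usd=abs_unrounded,
                rel_pct_unrounded=100.0 * abs_unrounded / ref.total_unrounded,
                abs_rounded_busd=abs_rounded,
                rel_pct_rounded=100.0 * abs_rounded / ref.total_reported,
            )
    return ResultsMatrix(results=results, reference=reference, savings=savings)


# ---------------------------------------------------------------------------
# rendering


def _fmt_days(x: float) -> str:
    # exact whole-day turnarounds print as integers; fractional weighted
    # averages print at 1 dp (so an exact 12 is "12" but 2.982 is "3.0")
    nearest = round(x)
    if abs(x - nearest) < 1e-9:
        return str(int(nearest))
    return f"{round_half_up(x, 1):.1f}"


def render(matrix: ResultsMatrix, format: str = "markdown") -> str:
    """Deterministic, byte-stable rendering of a results matrix.

    ``csv`` and ``json`` carry full precision and round-trip exactly;
    ``markdown`` applies display rounding (billions at 2 dp, days at 1 dp,
    percents at 0 dp, all half-up).
    """
    if format == "csv":
        buf = io.StringIO()
        matrix.to_frame().to_csv(buf, index=False)
        return buf.getvalue()
    if format == "json":
        frame = matrix.to_frame().set_index("strategy")
        payload = {
            "reference": matrix.reference,
            "strategies": json.loads(frame.to_json(orient="index")),
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if format == "markdown":
        return _render_markdown(matrix)
    raise ValueError(f"unknown format {format!r}; expected csv, markdown or json")


_MARKDOWN_ROWS = (
    ("total", "Total cost of testing and first-line therapy ($B)"),
    ("chemotherapy", "Cost of chemotherapy +/- targeted therapy ($B)"),
    ("immunotherapy", "Cost of immunotherapy ($B)"),
    ("testing", "Cost of testing ($B)"),
    ("savings_abs", "Cost savings vs reference ($B, rounded basis)"),
    ("savings_rel", "Cost savings vs reference (%, rounded basis)"),
    ("ttt_days", "Weighted average time to treatment initiation (days)"),
    ("pct_within_guideline", "Results within guideline window (%)"),
    ("pct_supported", "Therapy concordant with true status (%)"),
)


def _render_markdown(matrix: ResultsMatrix) -> str:
    names = matrix.strategy_names
    lines = ["| Metric | " + " | ".join(names) + " |"]
    lines.append("|" + " --- |" * (len(names) + 1))
    for key, label in _MARKDOWN_ROWS:
        cells = []
        for n in names:
            if key == "savings_abs":
                if matrix.reference is None:
                    cells.append("-")
                elif n == matrix.reference:
                    cells.append("Reference")
                else:
                    cells.append(f"{matrix.savings[n].abs_rounded_busd:.2f}")
            elif key == "savings_rel":
                if matrix.reference is None:
                    cells.append("-")
                elif n == matrix.reference:
                    cells.append("Reference")
                else:
                    cells.append(f"{matrix.savings[n].rel_pct_rounded:.1f}%")
            elif key == "ttt_days":
                cells.append(_fmt_days(matrix.results[n].outcomes.mean_days_to_treatment))
            elif key in ("pct_within_guideline", "pct_supported"):
                cells.append(f"{matrix.displayed(n, key):.0f}%")
            else:
                cells.append(f"{matrix.displayed(n, key):.2f}")
        lines.append(f"| {label} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# comparison with the published table


def printed_reference_table() -> dict:
    """The bundled published-values fixture (billions, days, percents)."""
    text = resources.files("msistrat.data").joinpath("table2_printed.json").read_text()
    return json.loads(text)


def paper_delta_report(matrix: ResultsMatrix) -> pd.DataFrame:
    """Per-cell computed-minus-printed differences at display precision.

    Cells the bundled fixture documents as internally inconsistent in the
    published table are flagged ``irreproducible``; a nonzero delta there is
    expected and reported, not an engine defect.
    """
    fixture = printed_reference_table()
    flagged = {tuple(cell) for cell in fixture["irreproducible"]}
    rows = []
    for name in matrix.strategy_names:
        for metric in _METRIC_ORDER:
            printed = fixture["metrics"].get(metric, {}).get(name)
            if printed is None:
                continue
            computed = matrix.displayed(name, metric)
            rows.append(
                {
                    "strategy": name,
                    "metric": metric,
                    "computed": computed,
                    "printed": float(printed),
                    "delta": round_half_up(computed - float(printed), 10),
                    "irreproducible": (name, metric) in flagged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["strategy", "metric", "computed", "printed", "delta", "irreproducible"],
    )
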