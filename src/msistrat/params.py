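"""Model parameters: types, validation, file I/O and derived quantities.

Every symbol of the budget-impact model lives here: the size and genotype
mix of the annual U.S. de novo metastatic colorectal cancer (mCRC) cohort,
the operating points, per-patient costs and turnaround times of the five
diagnostic assays (NGS, a high-sensitivity and a high-specificity PCR/IHC
panel, and a histopathology AI classifier at two ROC cutoffs), the
pembrolizumab dosing/cost schedule for dMMR/MSI-H disease, and the
share-weighted 5-FU-based chemotherapy mix for pMMR/MSS disease.

Two weighted chemotherapy aggregates (monthly cost, median duration) are
consumed as direct parameters rather than recomputed from their components:
the canonical published inputs carry a small internal inconsistency between
the aggregate and its components (printed $7,625.88/month vs recomputed
$7,622.38), and downstream cost cells are consistent with the aggregate.
The recomputation helpers remain available for sensitivity analyses.
"""

from __future__ import annotations

import json
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Annotated, Iterable, Sequence

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

from .rounding import round_half_up

__all__ = [
    "PopulationParams",
    "Assay",
    "PembroParams",
    "RegimenComponent",
    "ChemoParams",
    "GuidelineParams",
    "ModelConfig",
    "FpDosePriceBasis",
    "FnCostPolicy",
    "ConfigError",
    "load_model_config",
    "save_model_config",
    "table1_defaults",
    "derive_cohort_size",
    "weighted_monthly_chemo_cost",
    "weighted_median_duration",
    "panel_cost_sum",
]

_SHARE_TOL = 1e-9

Proportion = Annotated[float, Field(ge=0.0, le=1.0)]
NonNegative = Annotated[float, Field(ge=0.0)]


class ConfigError(ValueError):
    """A configuration file could not be read or failed validation."""


class FpDosePriceBasis(str, Enum):
    """How a false positive's short pembrolizumab exposure is priced.

    ``monthly_rate_per_dose``: each of the discontinuation doses is billed at
    the full monthly rate (default; consistent with the published cost cells).
    ``pro_rata``: doses are billed pro rata over the 0.69-month dose interval.
    """

    monthly_rate_per_dose = "monthly_rate_per_dose"
    pro_rata = "pro_rata"


class FnCostPolicy(str, Enum):
    """Which misclassified patients accrue chemotherapy cost.

    ``tn_only``: only true negatives (default; reproduces the published
    chemotherapy cells, under which false negatives accrue no drug cost).
    ``tn_plus_fn``: false negatives also receive the full chemotherapy
    course — the clinically complete accounting.
    """

    tn_only = "tn_only"
    tn_plus_fn = "tn_plus_fn"


class _Base(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class PopulationParams(_Base):
    """Annual U.S. mCRC cohort definition."""

    annual_incidence: Annotated[int, Field(gt=0)] = 147_950
    metastatic_fraction: Proportion = 0.22
    msih_prevalence: Proportion = 0.05

    @property
    def mss_prevalence(self) -> float:
        return 1.0 - self.msih_prevalence


class Assay(_Base):
    """One diagnostic test's operating point, per-patient cost and turnaround."""

    name: str
    sensitivity: Proportion
    specificity: Proportion
    cost_per_patient: NonNegative
    turnaround_days: NonNegative


class PembroParams(_Base):
    """Pembrolizumab cost and dosing cadence for dMMR/MSI-H patients.

    ``full_course_months`` defaults to 24.15 months = 35 doses at the
    0.69-month dose interval, the protocol cap of the pivotal first-line
    trial; it is not itself a published table row and is configurable.
    """

    monthly_cost: NonNegative = 23_021.13
    dose_interval_months: NonNegative = 0.69
    doses_before_first_scan: Annotated[int, Field(ge=0)] = 3
    full_course_months: NonNegative = 24.15
    scan_interval_months: NonNegative = 2.07
    fp_discontinuation_doses: Annotated[int, Field(ge=0)] = 3
    fp_dose_price_basis: FpDosePriceBasis = FpDosePriceBasis.monthly_rate_per_dose

    @model_validator(mode="after")
    def _course_covers_first_scan(self) -> "PembroParams":
        floor = self.doses_before_first_scan * self.dose_interval_months
        if self.full_course_months < floor - 1e-9:
            raise ValueError(
                "full_course_months must cover the doses before first restaging "
                f"({self.full_course_months} < {floor})"
            )
        return self


class RegimenComponent(_Base):
    """One regimen in the pMMR/MSS first-line chemotherapy mix."""

    name: str
    share: Proportion
    monthly_cost: NonNegative
    per_dose_cost: NonNegative = 0.0
    median_months_on_therapy: NonNegative = 0.0


class ChemoParams(_Base):
    """Share-weighted 5-FU-based chemotherapy parameters for pMMR/MSS patients."""

    components: tuple[RegimenComponent, ...]
    weighted_monthly_cost: NonNegative = 7_625.88
    weighted_median_months: NonNegative = 9.0
    weighted_per_dose_cost: NonNegative = 3_807.68
    dose_interval_months: NonNegative = 0.46
    doses_before_first_scan: Annotated[int, Field(ge=0)] = 5
    fn_cost_policy: FnCostPolicy = FnCostPolicy.tn_only

    @field_validator("components")
    @classmethod
    def _shares_sum_to_one(
        cls, v: tuple[RegimenComponent, ...]
    ) -> tuple[RegimenComponent, ...]:
        if v:
            total = sum(c.share for c in v)
            if abs(total - 1.0) > _SHARE_TOL:
                raise ValueError(f"component shares must sum to 1, got {total!r}")
        return v


class GuidelineParams(_Base):
    """Guideline-recommended maximum turnaround from sample receipt to result."""

    max_working_days: Annotated[float, Field(gt=0)] = 10.0


class ModelConfig(_Base):
    """Complete, validated parameter set for the strategy-evaluation pipeline."""

    population: PopulationParams = PopulationParams()
    assays: dict[str, Assay]
    pembro: PembroParams = PembroParams()
    chemo: ChemoParams
    guideline: GuidelineParams = GuidelineParams()
    reporting_scale: str = "billions_2dp"

    def assay(self, name: str) -> Assay:
        try:
            return self.assays[name]
        except KeyError:
            raise ConfigError(
                f"assay {name!r} is not defined; available: {sorted(self.assays)}"
            ) from None

    @property
    def cohort_size(self) -> int:
        return derive_cohort_size(self.population)


# ---------------------------------------------------------------------------
# derived quantities


def derive_cohort_size(p: PopulationParams) -> int:
    """Annual de novo metastatic cohort: incidence x metastatic fraction.

    Rounded half-up to a whole patient count; downstream expected counts are
    kept fractional.
    """
    return int(round_half_up(p.annual_incidence * p.metastatic_fraction))


def weighted_monthly_chemo_cost(components: Sequence[RegimenComponent]) -> float:
    """Share-weighted mean monthly cost of the chemotherapy mix, full precision."""
    _check_shares(components)
    return sum(c.share * c.monthly_cost for c in components)


def weighted_median_duration(components: Sequence[RegimenComponent]) -> float:
    """Share-weighted mean of the component median times on therapy (months)."""
    _check_shares(components)
    return sum(c.share * c.median_months_on_therapy for c in components)


def panel_cost_sum(component_costs: Iterable[float]) -> float:
    """Total per-patient panel cost as the sum of its marker components."""
    costs = list(component_costs)
    for c in costs:
        if c < 0:
            raise ValueError(f"panel component cost must be >= 0, got {c!r}")
    return sum(costs)


def _check_shares(components: Sequence[RegimenComponent]) -> None:
    total = sum(c.share for c in components)
    if abs(total - 1.0) > _SHARE_TOL:
        raise ValueError(f"component shares must sum to 1, got {total!r}")


# ---------------------------------------------------------------------------
# file I/O


def table1_defaults() -> ModelConfig:
    """The packaged canonical parameter set (the published model inputs)."""
    text = resources.files("msistrat.data").joinpath("table1_defaults.yaml").read_text()
    return _config_from_mapping(yaml.safe_load(text), source="<packaged defaults>")


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML or JSON model configuration.

    Keys mirror the :class:`ModelConfig` field tree; omitted optional fields
    take the packaged defaults. Raises :class:`ConfigError` naming the
    offending key on schema or invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _config_from_mapping(raw, source=str(path))


def _config_from_mapping(raw: dict, source: str) -> ModelConfig:
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"invalid config ({source}): " + "; ".join(lines)) from exc


def save_model_config(config: ModelConfig, path: str | Path) -> None:
    """Write a config as YAML (or JSON for a ``.json`` path); round-trips exactly."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
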