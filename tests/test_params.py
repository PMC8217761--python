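"""Parameter types, derived quantities, validation and config I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msistrat import (
    ConfigError,
    PopulationParams,
    RegimenComponent,
    derive_cohort_size,
    load_model_config,
    panel_cost_sum,
    save_model_config,
    table1_defaults,
    weighted_median_duration,
    weighted_monthly_chemo_cost,
)


def test_packaged_defaults_carry_canonical_inputs(config):
    assert config.pembro.monthly_cost == 23021.13
    assert config.chemo.weighted_monthly_cost == 7625.88
    assert config.chemo.weighted_median_months == 9.0
    assert config.cohort_size == 32549
    assert set(config.assays) == {
        "ngs", "panel_high_sens", "panel_high_spec", "ai_high_sens", "ai_high_spec",
    }
    ngs = config.assay("ngs")
    assert (ngs.sensitivity, ngs.specificity) == (1.0, 1.0)
    assert ngs.cost_per_patient == 3500.00 and ngs.turnaround_days == 12
    # AI turnaround is the assumed nominal value of zero days
    assert config.assay("ai_high_sens").turnaround_days == 0


@pytest.mark.parametrize(
    "incidence, fraction, expected",
    [
        (147_950, 0.22, 32_549),
        (100, 1.0, 100),
        (12_345, 0.5, 6_173),  # 6172.5 rounds half-up
    ],
)
def test_cohort_size_rounds_half_up(incidence, fraction, expected):
    p = PopulationParams(
        annual_incidence=incidence, metastatic_fraction=fraction, msih_prevalence=0.05
    )
    assert derive_cohort_size(p) == expected


def test_weighted_chemo_aggregates_recomputed_from_components(config):
    comps = config.chemo.components
    # recomputation differs from the canonical printed aggregate (7625.88),
    # which is why the aggregate is consumed as a direct parameter
    assert weighted_monthly_chemo_cost(comps) == pytest.approx(7622.3755)
    assert weighted_median_duration(comps) == pytest.approx(8.985)


@pytest.mark.parametrize(
    "shares_costs_medians, expected_cost, expected_months",
    [
        ([(1.0, 100.0, 4.4)], 100.0, 4.4),
        ([(0.5, 0.0, 8.0), (0.5, 200.0, 10.0)], 100.0, 9.0),
    ],
)
def test_weighted_aggregates_simple_mixes(shares_costs_medians, expected_cost, expected_months):
    comps = [
        RegimenComponent(
            name=f"c{i}", share=s, monthly_cost=c, median_months_on_therapy=m
        )
        for i, (s, c, m) in enumerate(shares_costs_medians)
    ]
    assert weighted_monthly_chemo_cost(comps) == pytest.approx(expected_cost)
    assert weighted_median_duration(comps) == pytest.approx(expected_months)


def test_weighted_aggregates_reject_bad_share_sum():
    comps = [
        RegimenComponent(name="a", share=0.5, monthly_cost=1.0),
        RegimenComponent(name="b", share=0.6, monthly_cost=1.0),
    ]
    with pytest.raises(ValueError, match="sum to 1"):
        weighted_monthly_chemo_cost(comps)


@settings(derandomize=True, max_examples=50)
@given(
    data=st.lists(
        st.tuples(
            st.floats(0.01, 1.0), st.floats(0, 1e5), st.floats(0, 24)
        ),
        min_size=1,
        max_size=6,
    ),
    seed=st.randoms(use_true_random=False),
)
def test_weighted_aggregates_invariant_to_ordering(data, seed):
    total = sum(s for s, _, _ in data)
    comps = [
        RegimenComponent(
            name=f"c{i}", share=s / total, monthly_cost=c, median_months_on_therapy=m
        )
        for i, (s, c, m) in enumerate(data)
    ]
    shuffled = list(comps)
    seed.shuffle(shuffled)
    assert weighted_monthly_chemo_cost(shuffled) == pytest.approx(
        weighted_monthly_chemo_cost(comps)
    )
    assert weighted_median_duration(shuffled) == pytest.approx(
        weighted_median_duration(comps)
    )


@settings(derandomize=True, max_examples=100)
@given(
    inc=st.integers(1, 10**6),
    d_inc=st.integers(0, 10**4),
    frac=st.floats(0.0, 1.0),
    d_frac=st.floats(0.0, 1.0),
)
def test_cohort_size_monotone(inc, d_inc, frac, d_frac):
    hi_frac = min(1.0, frac + d_frac)
    base = derive_cohort_size(
        PopulationParams(annual_incidence=inc, metastatic_fraction=frac)
    )
    assert derive_cohort_size(
        PopulationParams(annual_incidence=inc + d_inc, metastatic_fraction=frac)
    ) >= base
    assert derive_cohort_size(
        PopulationParams(annual_incidence=inc, metastatic_fraction=hi_frac)
    ) >= base


@pytest.mark.parametrize(
    "costs, expected",
    [((682.29, 175.40, 348.56), 1206.25), ((), 0.0), ((1.0, 2.0), 3.0)],
)
def test_panel_cost_sums_marker_components(costs, expected):
    assert panel_cost_sum(costs) == pytest.approx(expected)


def test_panel_cost_rejects_negative():
    with pytest.raises(ValueError):
        panel_cost_sum([1.0, -0.5])


def test_config_round_trips_yaml_and_json(config, tmp_path):
    for name in ("cfg.yaml", "cfg.json"):
        path = tmp_path / name
        save_model_config(config, path)
        assert load_model_config(path) == config


def test_missing_config_file_reports_path(tmp_path):
    with pytest.raises(ConfigError, match="not found"):
        load_model_config(tmp_path / "nope.yaml")


def test_invalid_sensitivity_names_field(config, tmp_path):
    raw = config.model_dump(mode="json")
    raw["assays"]["ngs"]["sensitivity"] = 1.2
    path = tmp_path / "bad.json"
    import json

    path.write_text(json.dumps(raw))
    with pytest.raises(ConfigError, match="sensitivity"):
        load_model_config(path)


def test_bad_component_share_sum_rejected(config, tmp_path):
    raw = config.model_dump(mode="json")
    raw["chemo"]["components"][0]["share"] = 0.5
    raw["chemo"]["components"][1]["share"] = 0.5
    raw["chemo"]["components"][2]["share"] = 0.2
    path = tmp_path / "bad.yaml"
    import yaml

    path.write_text(yaml.safe_dump(raw))
    with pytest.raises(ConfigError, match="sum to 1"):
        load_model_config(path)


def test_defaults_are_cached_free_and_fresh():
    a, b = table1_defaults(), table1_defaults()
    assert a == b
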