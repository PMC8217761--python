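"""Microsimulation oracle and probabilistic sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from msistrat import (
    PsaDistributionSpec,
    build_results_matrix,
    builtin_strategies,
    draw_psa_parameters,
    evaluate_costs,
    evaluate_outcomes,
    run_psa,
    simulate_cohort,
)


def test_same_seed_reproduces_records(config, strategies):
    a = simulate_cohort(strategies["E"], config, n=5000, seed=42)
    b = simulate_cohort(strategies["E"], config, n=5000, seed=42)
    pd.testing.assert_frame_equal(a.patients, b.patients)
    assert a.costs == b.costs
    c = simulate_cohort(strategies["E"], config, n=5000, seed=43)
    assert not a.patients.equals(c.patients)


def test_rejects_nonpositive_n(config, strategies):
    with pytest.raises(ValueError):
        simulate_cohort(strategies["A"], config, n=0, seed=1)


def test_zero_prevalence_perfect_specificity_no_immunotherapy(config, strategies):
    cfg = config.model_copy(
        update={
            "population": config.population.model_copy(
                update={"msih_prevalence": 0.0}
            )
        }
    )
    result = simulate_cohort(strategies["A"], cfg, n=2000, seed=7)
    assert result.costs.immunotherapy == 0.0
    assert (result.patients["therapy_class"] == "chemotherapy").all()


def test_final_call_consistent_with_test_results(config, strategies):
    res = simulate_cohort(strategies["H"], config, n=20_000, seed=11)
    df = res.patients
    confirmed = df["confirm_result"] != ""
    # H confirms screen-positives: every confirmed patient screened positive,
    # and the final call is the conjunction of the two results
    assert (df.loc[confirmed, "screen_result"] == "positive").all()
    assert (
        df.loc[confirmed, "final_call"]
        == np.where(df.loc[confirmed, "confirm_result"] == "positive",
                    "positive", "negative")
    ).all()
    assert (df.loc[~confirmed, "final_call"] == "negative").all()


@pytest.mark.parametrize("name", list("ABCDEFGH"))
def test_microsim_agrees_with_deterministic_within_3se(config, strategies, name):
    """Brute-force oracle check at n=200,000: every deterministic output lies
    within 3 Monte Carlo standard errors of the simulated aggregate."""
    s = strategies[name]
    det_costs = evaluate_costs(s, config)
    det_out = evaluate_outcomes(s, config)
    res = simulate_cohort(s, config, n=200_000, seed=1)
    checks = {
        "testing": (det_costs.testing, res.costs.testing),
        "immunotherapy": (det_costs.immunotherapy, res.costs.immunotherapy),
        "chemotherapy": (det_costs.chemotherapy, res.costs.chemotherapy),
        "total": (det_costs.total_unrounded, res.costs.total_unrounded),
        "mean_days_to_treatment": (
            det_out.mean_days_to_treatment,
            res.outcomes.mean_days_to_treatment,
        ),
        "pct_within_guideline": (
            det_out.pct_within_guideline,
            res.outcomes.pct_within_guideline,
        ),
        "pct_supported": (det_out.pct_supported, res.outcomes.pct_supported),
    }
    for key, (det, sim) in checks.items():
        tol = 3 * res.standard_errors[key] + 1e-6 * abs(det)
        assert abs(det - sim) <= tol, (name, key, det, sim, tol)


def test_empirical_frequencies_converge(config, strategies):
    # tp/fp/fn/tn frequencies approach the closed-form partition as n grows
    from msistrat.costs import partition_cohort
    from msistrat.strategies import effective_characteristics

    s = strategies["D"]
    prev = config.population.msih_prevalence
    part = partition_cohort(1.0, prev, effective_characteristics(s))
    errs = []
    for n in (1000, 100_000):
        df = simulate_cohort(s, config, n=n, seed=3).patients
        pos = df["final_call"] == "positive"
        dis = df["true_status"] == "dMMR_MSI_H"
        emp = np.array(
            [(pos & dis).mean(), (pos & ~dis).mean(),
             (~pos & dis).mean(), (~pos & ~dis).mean()]
        )
        exact = np.array([part.tp, part.fp, part.fn, part.tn])
        errs.append(np.abs(emp - exact).max())
    assert errs[1] < errs[0]


def test_degenerate_psa_reproduces_point_estimate(config):
    spec = PsaDistributionSpec(base=config, proportion_rel_sd=0.0, cost_rel_sd=0.0,
                               seed=9)
    configs = draw_psa_parameters(spec, 3)
    assert all(c == config for c in configs)
    result = run_psa(builtin_strategies(config), configs, "A")
    matrix = build_results_matrix(config)
    for name, row in matrix.savings.items():
        draws = result.draws.query("strategy == @name")["savings_usd"]
        assert np.allclose(draws, row.abs_unrounded_usd)


def test_psa_draws_are_seed_reproducible_and_valid(config):
    spec = PsaDistributionSpec(base=config, seed=123)
    a = draw_psa_parameters(spec, 50)
    b = draw_psa_parameters(spec, 50)
    assert a == b
    # validity (proportions in [0,1], costs >= 0) is enforced by construction;
    # draws should actually vary
    prevs = {c.population.msih_prevalence for c in a}
    assert len(prevs) > 1


def test_psa_reference_savings_all_zero(config):
    spec = PsaDistributionSpec(base=config, seed=5)
    result = run_psa(builtin_strategies(config), draw_psa_parameters(spec, 10), "A")
    ref = result.draws.query("strategy == 'A'")["savings_usd"]
    assert (ref == 0.0).all()


def test_savings_ranking_preserved_under_pembro_price_shift(config):
    # raising only the immunotherapy price widens H's advantage over A
    # (H treats fewer patients with pembrolizumab than A does)
    pricier = config.model_copy(
        update={"pembro": config.pembro.model_copy(update={"monthly_cost": 30000.0})}
    )
    strategies = builtin_strategies(config)
    result = run_psa(strategies, [config, pricier], "A")
    h = result.draws.query("strategy == 'H'").sort_values("draw")["savings_usd"]
    assert h.iloc[1] > h.iloc[0] > 0


def test_run_psa_rejects_bad_inputs(config):
    strategies = builtin_strategies(config)
    with pytest.raises(ValueError):
        run_psa([], [config], "A")
    with pytest.raises(ValueError):
        run_psa(strategies, [], "A")
    with pytest.raises(ValueError):
        run_psa(strategies, [config], "Z")
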