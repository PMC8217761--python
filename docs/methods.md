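# Methods

## Model structure

`msistrat` is a deterministic decision-analytic (budget-impact) model over
one year, from the perspective of the U.S. healthcare system, with no
discounting. The unit of analysis is the annual de novo metastatic
colorectal cancer cohort, N = round(147,950 × 0.22) = 32,549 patients, of
whom a fraction π = 0.05 are dMMR/MSI-H. A testing strategy maps each
patient, through one or two Bernoulli-accurate tests, to a final
positive/negative MMR/MSI call; positives start pembrolizumab, negatives
start the 5-FU-based chemotherapy mix. All cohort quantities are expected
values computed in closed form on the confusion partition
(TP/FP/FN/TN); expected counts are fractional patients and currency is
carried at full precision, rounded only for display.

Two-stage strategies compose operating points by standard serial-testing
algebra (see README). The model assumes conditional independence of test
errors given true disease status; correlated errors between the AI
classifier and the panel/NGS are out of scope. Treatment begins only after
every test on the patient's path has resulted — no treat-while-confirming —
so a path's time to treatment is the sum of its tests' turnarounds, with no
shipping or scheduling latency beyond the printed turnaround values.

## Parameters

All defaults live in `src/msistrat/data/table1_defaults.yaml`
(USD; turnarounds in days; durations in months):

| Parameter | Default | Notes |
| --- | --- | --- |
| Annual CRC incidence | 147,950 | U.S., SEER-derived |
| Metastatic fraction | 0.22 | |
| dMMR/MSI-H prevalence | 0.05 | of metastatic disease |
| NGS | Se 1.00, Sp 1.00, $3,500, 12 d | conservative perfect-test assumption |
| Panel, high-sens cutoff | Se 1.00, Sp 0.81, $1,206.25, 4 d | panel cost = KRAS/NRAS $682.29 + BRAF $175.40 + MSI $348.56 |
| Panel, high-spec cutoff | Se 0.67, Sp 0.93, $1,206.25, 4 d | |
| AI, high-sens cutoff | Se 0.98, Sp 0.79, $6.07, 0 d | turnaround is a nominal assumed 0 |
| AI, high-spec cutoff | Se 0.70, Sp 0.98, $6.07, 0 d | |
| Pembrolizumab monthly cost | $23,021.13 | dose interval 0.69 mo; 3 doses before first restaging |
| Pembrolizumab full course | 24.15 mo | 35 doses × 0.69 mo, the pivotal-trial protocol cap; not itself a published row — configurable |
| Chemo weighted monthly cost | $7,625.88 | consumed directly (see below) |
| Chemo weighted median duration | 9.0 mo | consumed directly; recomputes to 8.985 |
| FP discontinuation | 3 doses at the monthly rate | configurable to pro-rata (3 × 0.69 × monthly) |
| FN chemotherapy cost | none (`tn_only`) | `tn_plus_fn` gives the clinically complete accounting |
| Guideline window | 10 working days | printed turnarounds compared directly; the working-day vs calendar-day distinction is ignored |

Two published aggregates are internally inconsistent with their own
components: the weighted monthly chemotherapy cost prints as $7,625.88 but
recomputes to $7,622.38 from the printed shares (35/45/20%) and component
costs, and the weighted per-dose cost prints as $3,807.68 vs a recomputed
$3,805.59. Because the published cost cells are consistent with the printed
aggregates, the engine consumes the aggregates as direct parameters; the
recomputation helpers (`weighted_monthly_chemo_cost`,
`weighted_median_duration`) exist for sensitivity analyses.

## Strategy definitions

The built-in strategies follow the published decision-tree figure: E, G and
H confirm AI-**positives** (with NGS, the high-sensitivity panel and the
high-specificity panel respectively); F confirms AI-**negatives** with NGS.
The published Methods paragraph and abstract describe E/F with the arms
swapped; the figure reading is used because it reproduces the published
testing-cost and time-to-treatment cells for E ($0.03B, 3.0 d) and F
($0.11B, 11.4 d), which the alternative reading does not. The `Strategy`
constructor accepts either arm, so the alternative reading remains
expressible.

## Reproduction of the published table, and its inconsistent cells

Display rounding is half-up throughout: dollars at billions/2 dp, days at
1 dp, percents at 0 dp; the reported total is the sum of the three
already-rounded components, the convention under which the published
component cells sum to the published totals (the unrounded NGS-alone total
is ≈$3.141B; the printed components sum to $3.13B).

Under these conventions the engine reproduces the published reference
column exactly (testing $0.11B, immunotherapy $0.90B, chemotherapy $2.12B,
total $3.13B, 12 days, 0% within guideline, 100% concordance), the derived
input rows (32,549; $1,206.25; 9.0 months), the high-specificity-panel and
high-specificity-AI chemotherapy cells ($1.97B, $2.08B), the 97%/31,442
concordance of high-specificity AI, and E/F time-to-treatment and
within-guideline cells.

A minority of published cells cannot be reproduced from the published
inputs under any coherent sequential-testing model; the bundled fixture
(`data/table2_printed.json`) flags them and `paper_delta_report` prints the
per-cell difference instead of matching:

* **B chemotherapy ($1.70B printed)** — the printed 81% panel specificity
  gives $1.72B; $1.70B would require ≈80%.
* **No single full-course length fits all immunotherapy cells.** 24.15
  months reproduces A/B/C ($0.90/$1.31/$0.76B) but yields D $0.68 vs
  printed $0.67, E $0.89 vs $0.88 and F $0.95 vs $0.94; 24.0 months flips
  which cells match. The default is 24.15 (the protocol cap); the 1-cent
  deltas are reported.
* **F chemotherapy ($2.07B printed)** — F's true-negative mass is identical
  to D's, which prints $2.08B in the same table.
* **E concordance (80% printed)** — consistent only with treating
  AI-positives before NGS confirmation, which contradicts the same column's
  testing cost and time-to-treatment; the engine's convention gives 99.9%.
* **G/H time to treatment (1.6/1.2 d printed)** — additive turnarounds give
  0.994 d for both.
* **G/H cost and concordance cells** — the printed values equal applying
  the confirm panel to the whole cohort, ignoring the AI screen; under the
  sequential model G/H chemo are $2.04/$2.09B and concordance 96/97%.
* **Concordance display** — printed B 81% and C 91% correspond to truncating
  81.95/91.70 while printed D 97% rounds 96.6; no single display convention
  fits, so half-up is used everywhere (B→82, C→92). F prints 97% where the
  accuracy identity forces 98.1%.

The headline comparison is robust to all of this: strategy H is the
cheapest under every convention considered, with savings vs NGS-alone of
$0.40B / 12.8% on the rounded-component basis and $0.414B / 13.2% on the
unrounded basis, bracketing the published $400M / 12.9% (whose exact basis
is not recoverable). Both bases are computed and stored; the unrounded one
is the package's default headline.

## Microsimulation oracle

`simulate_cohort` realises the model patient-by-patient: Bernoulli(π)
disease status, Bernoulli test results at the assay operating points, and
per-patient costs under the identical accounting conventions, with
aggregates scaled by N/n. It exists to verify the closed-form engine, and
the acceptance suite requires every deterministic output (three cost
components, time to treatment, both percentages) to lie within 3 Monte
Carlo standard errors of the simulated aggregate for all eight strategies
at n = 200,000 across five seeds. Standard errors are sample-based
(per-patient SD/√n, binomial for proportions). The simulator emulates only
what the deterministic model assumes — independent errors, homogeneous
costs, fixed durations; it does not add patient heterogeneity, so
agreement validates the expected-value algebra, not the model's realism.

Randomness comes from one `numpy.random.default_rng(seed)`; the
status/screen/confirm uniforms are drawn as whole arrays up front (confirm
draws are generated for every patient and consumed only on the confirm
arm), making results independent of iteration order.

## Probabilistic sensitivity analysis

The published model is a point estimate; the PSA layer is this package's
extension. `PsaDistributionSpec` draws proportions (prevalence,
sensitivities, specificities) from moment-matched beta distributions and
costs (per-test, pembrolizumab monthly, weighted chemo monthly) from gamma
distributions, each with 10% relative standard deviation by default — a
conventional health-economics choice, not a published input. Means at 0 or
1 (and zero relative SD) are kept degenerate, which also gives the exact
point-estimate reduction used as a correctness check. Durations and dosing
cadence are held fixed. `run_psa` reports per-draw totals and savings vs
the reference with 2.5/50/97.5% quantiles.

## Numerical choices and degenerate inputs

* Rounding is half-up via `decimal.Decimal` (never banker's); cohort size
  is the only internally rounded quantity (to whole patients).
* Branch enumeration drops zero-probability paths and asserts the
  surviving fractions sum to 1 within 1e-9; regimen shares must sum to 1
  within 1e-9.
* Prevalence 0 or 1 and perfect operating points are all well-defined
  (e.g. prevalence 0 with a perfect screen leaves a single all-negative
  branch); `partition_cohort` requires N > 0, `simulate_cohort` n > 0.
* Markdown day cells print as integers when the exact weighted average is
  within 1e-9 of a whole day, else at 1 dp.

## Problem sizes

The default verification sizes — 200,000 simulated patients per
strategy/seed for the oracle comparison and 500 PSA draws in the
acceptance script — were chosen so Monte Carlo error is far below the
effects of interest (the 3-SE band on a $B-scale total is ≈$0.02B) while
the whole pipeline recomputes in seconds.

## Known limitations

The model inherits the published design: one-year horizon, no discounting,
no ICERs or survival/QALY modelling, no second-line, adverse-event,
imaging or administration costs, a monolithic payer perspective, and no AI
development or deployment cost. False positives accrue no chemotherapy
cost after discontinuing pembrolizumab and false negatives no rescue
immunotherapy. Three-or-more-stage strategies and marker-specific reflex
routing are not modelled; the chemotherapy mix shares absorb KRAS/BRAF
routing.
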