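# msistrat

A budget- and clinical-impact model of mismatch-repair / microsatellite-
instability (MMR/MSI) testing strategies for first-line metastatic
colorectal cancer (mCRC), written for health-economics and molecular-
pathology researchers who want to compare diagnostic pathways — including
histopathology-AI screening — on cost, turnaround and diagnostic accuracy
over the annual U.S. de novo mCRC cohort.

## The model

About 5% of de novo mCRC is dMMR/MSI-H and benefits from first-line
pembrolizumab; the other 95% (pMMR/MSS) receives 5-FU-based chemotherapy ±
targeted agents. A testing strategy decides, per patient, which therapy the
genotype call supports. `msistrat` evaluates single-stage strategies and
two-stage screen/confirm strategies in which one arm of the screening
result is re-tested before the final call.

For a screen (Se₁, Sp₁) confirmed on positives by (Se₂, Sp₂), standard
serial-testing algebra gives the composed operating point

    Se = Se₁·Se₂          Sp = 1 − (1 − Sp₁)(1 − Sp₂)

and, confirming negatives,

    Se = Se₁ + (1 − Se₁)·Se₂          Sp = Sp₁·Sp₂.

With cohort size N and prevalence π the expected confusion partition is
TP = NπSe, FN = Nπ(1 − Se), FP = N(1 − π)(1 − Sp), TN = N(1 − π)Sp, and

* testing cost = N × (screen cost + P(enter confirm arm) × confirm cost),
* immunotherapy cost = TP × c_pembro × full-course months
  + FP × (discontinuation doses × c_pembro),
* chemotherapy cost = TN × weighted monthly chemo cost × weighted median
  months on therapy,

plus three clinical metrics: branch-weighted mean time to treatment
initiation (summed turnarounds per path), percent of patients resulted
within the guideline 10-working-day window, and percent whose final therapy
is concordant with their true MMR/MSI status, which equals the
prevalence-weighted accuracy 100 × (π·Se + (1 − π)·Sp).

Eight built-in strategies (A–H) combine NGS, high-sensitivity and
high-specificity PCR/IHC panels, and an AI classifier read at a
high-sensitivity and a high-specificity ROC cutoff. A patient-level Monte
Carlo microsimulation reproduces the deterministic engine as a brute-force
oracle, and a probabilistic sensitivity analysis (beta/gamma parameter
draws) propagates parameter uncertainty to the savings estimates. The
packaged default configuration carries the canonical published inputs;
every parameter is overridable from a YAML/JSON file. A bundled fixture of
the published results table drives a per-cell delta report, with the cells
known to be internally inconsistent in the published table flagged rather
than matched (see `docs/methods.md`).

## Worked example

```python
from msistrat import table1_defaults, build_results_matrix, render

config = table1_defaults()
matrix = build_results_matrix(config, reference="A")
print(render(matrix, "markdown"))
```

prints (abridged to four of the eight strategies):

| Metric | A | C | D | H |
| --- | --- | --- | --- | --- |
| Total cost of testing and first-line therapy ($B) | 3.13 | 2.77 | 2.76 | 2.73 |
| Cost of chemotherapy +/- targeted therapy ($B) | 2.12 | 1.97 | 2.08 | 2.09 |
| Cost of immunotherapy ($B) | 0.90 | 0.76 | 0.68 | 0.63 |
| Cost of testing ($B) | 0.11 | 0.04 | 0.00 | 0.01 |
| Cost savings vs reference ($B, rounded basis) | Reference | 0.36 | 0.37 | 0.40 |
| Cost savings vs reference (%, rounded basis) | Reference | 11.5% | 11.8% | 12.8% |
| Weighted average time to treatment initiation (days) | 12 | 4 | 0 | 1.0 |
| Results within guideline window (%) | 0% | 100% | 100% | 100% |
| Therapy concordant with true status (%) | 100% | 92% | 97% | 97% |

Strategy A is NGS alone (the reference): every one of the 32,549 annual
patients gets a perfect but slow ($3,500, 12-day) test, for $3.13B in
first-year testing plus first-line drug cost. Strategy H — AI screening at
the high-sensitivity cutoff with high-specificity panel confirmation of
AI-positives — is the cheapest at $2.73B, saving $0.40B (12.8%) while
treating 97% of patients concordantly with a 1-day average wait. Strategy D
(high-specificity AI alone) gives the best clinical trade-off: near-zero
testing cost, immediate results, 97% concordance (31,442 of 32,549
patients).

The same pipeline is available from the shell:

```sh
msistrat run --format markdown          # the matrix above
msistrat delta                          # per-cell comparison vs the published table
msistrat microsim --strategy H --n 200000 --seed 1 --out patients.csv
msistrat psa --draws 1000 --seed 1     # savings quantiles under parameter uncertainty
```

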