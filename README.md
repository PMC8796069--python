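# subtyperisk

Statistical machinery for studying how rare germline variants in breast
cancer susceptibility genes (*ATM*, *BARD1*, *BRCA1*, *BRCA2*, *CHEK2*,
*PALB2*, *RAD51C*, *RAD51D*, *TP53*) shape the **intrinsic-like subtype** of
the tumors their carriers develop — and what that implies for
subtype-specific absolute risk.

Individual-level data for studies of this kind are access-controlled, so the
package is built around a **synthetic cohort generator** that emulates the
relevant data structure: a large case-control study (tens of thousands of
women aged 18–79 from several countries), rare carriers (frequencies
0.05%–1%), subtype-specific odds ratios with log-linear age trends, and
heavy missingness in the pathology markers (ER 18%, grade 18%, PR 32%,
ERBB2 43%).  Every analysis stage is then testable against known generating
values.

## What it computes

Five intrinsic-like subtypes are defined from immunohistochemistry and
grade: HR status is positive iff ER or PR is positive, grades 1–2 count as
low/intermediate and grade 3 as high, giving HR+/ERBB2− low-grade,
HR+/ERBB2− high-grade, HR+/ERBB2+, HR−/ERBB2+ and triple-negative (TN).

* **Association** (`subtyperisk.association`) — case-control multinomial
  logistic regression with controls as the reference outcome, so each
  coefficient is a subtype-vs-control log-OR for carrier status, adjusted
  for age and country.  The likelihood is maximized by a Newton iteration
  written in this package (no GLM library behind it), with support for row
  weights and linear constraints; that one core also provides binary
  logistic models, the ordered-trend model (log OR linear in outcome
  level), age × carrier interaction models, and the case-only
  likelihood-ratio test of etiologic heterogeneity.
* **Imputation** (`subtyperisk.imputation`) — missing markers are handled
  two ways and cross-validated against each other: Multiple Imputation by
  Chained Equations (m completed data sets, estimates pooled with Rubin's
  rules, T = W + (1 + 1/m)B) and an EM algorithm for the joint distribution
  of the 24 (ER, PR, ERBB2, grade) cells, whose per-case posteriors weight
  the regression directly.
* **Absolute risk** (`subtyperisk.risk`) — subtype-specific carrier risk
  curves from population incidence μ(t), subtype proportions π_s(t),
  carrier frequency p and ORs: the noncarrier baseline hazard is
  constrained so the population mixture reproduces μ(t)·π_s(t) exactly,
  λ⁰_s(t) = μ(t)π_s(t) / (p·OR_s(t) + 1 − p), and cumulative risks use the
  discrete product-limit form with competing risk from the other subtypes,
  F_s(T) = Σ_{t<T} h_s(t)·S(t), Σ_s F_s + S = 1.
* **Carrier burden** (`subtyperisk.burden`) — the share of cases in an
  age group × subtype cell who carry a variant,
  p·OR / (p·OR + 1 − p), analytically and by counting.

## Worked example

```python
from subtyperisk import single_gene_config, generate_cohort
from subtyperisk.subtyping import classify_dataframe
from subtyperisk.association import fit_multinomial_cc

cfg = single_gene_config("BRCA1", carrier_freq=0.01, age_trend=1.0,
                         n_cases=100_000, n_controls=100_000, seed=1,
                         missingness={"er": 0, "pr": 0, "erbb2": 0, "grade": 0})
cohort = classify_dataframe(generate_cohort(cfg))
fit = fit_multinomial_cc(cohort, "BRCA1")
print(fit.or_table("carrier", "BRCA1")[["outcome_category", "OR", "ci_low", "ci_high"]])
```

prints

```
      outcome_category         OR     ci_low    ci_high
0   HRpos_ERBB2neg_low   3.291157   3.040877   3.562037
1  HRpos_ERBB2neg_high  13.040750  12.044608  14.119278
2       HRpos_ERBB2pos   2.340152   2.012529   2.721109
3       HRneg_ERBB2pos   9.570009   8.523055  10.745569
4                   TN  54.960813  51.339845  58.837164
```

— the fitted subtype-vs-control ORs for carriers, recovering the generating
values (3.26, 13.5, 2.27, 9.85, 55.32) within sampling error.  The TN
estimate of ≈55 says a BRCA1-class carrier has ~55-fold the odds of a
noncarrier of developing triple-negative disease.

## Analysis scripts and CLI

`analysis/01_simulate_cohort.py` … `06_carrier_burden.py` run the full
narrative on a desk-scale cohort, writing tables under `results/`:
simulate → classify subtypes → impute (chained equations + EM) → fit
association models → risk curves → carrier-burden table.  The same stages
are available as a CLI:

```bash
subtyperisk write-config --out config.yaml
subtyperisk run-all --config config.yaml --out run1 --seed 11 --m 10
```

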