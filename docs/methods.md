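# Methods

## The scientific problem

Carriers of rare protein-truncating variants (PTVs) or rare pathogenic
missense variants (MSVs) in breast cancer susceptibility genes do not
develop a random cross-section of breast tumors: the distribution over
intrinsic-like subtypes differs sharply by gene.  Quantifying that
heterogeneity requires (i) a subtype definition computable from routinely
collected immunohistochemistry, (ii) regression machinery for
subtype-vs-control odds ratios from case-control data with rare exposure,
(iii) principled handling of heavily missing pathology markers, and (iv) a
way to turn relative risks into subtype-specific cumulative (absolute)
risks for carriers.  This package implements all four stages and a
synthetic cohort generator that makes the whole chain testable with known
truth, since real cohorts of this kind are access-controlled.

## Subtype classification

Five intrinsic-like subtypes are defined from ER, PR, ERBB2 and grade.
Hormone-receptor (HR) status is positive iff ER or PR is positive and
negative only when both are observed negative; if one receptor is missing
and the other negative, HR status is unresolved and the case is
`undetermined` — the classifier never guesses an unobserved marker.  The
HR+/ERBB2− group splits by grade (1–2 low/intermediate, 3 high); the
ERBB2+ groups and triple-negative (TN) disease do not require grade.  The
classifier is total and, on fully observed markers, partitions the 24
marker cells into exactly the five subtypes.  Published subtype
definitions of this family do not always pin down every edge convention;
the HR-resolution convention above is this package's own (conservative)
choice and is documented as such.

## Synthetic cohort generator

The generator emulates a multi-country case-control study of women aged
18–79 (truncated-normal ages: cases mean 55.8, SD 10.6; controls mean
55.1, SD 11.9), with per-gene carrier frequencies below 1%, mutually
exclusive carrier states (multi-gene carriers are excluded from studies of
this design), and an MSV share (default 20%) for BRCA1/BRCA2/TP53 that
carries the same ORs as PTVs.

The causal structure is the standard rare-disease model.  Controls carry
at the population frequency p_g.  For a case of age a, the odds of
carrying gene g are the population odds times
C_g(a) = Σ_s π_s·OR_{g,s}·θ_g^(a−50), where π_s is the subtype
distribution of noncarrier cases, OR_{g,s} the subtype-specific odds ratio
at the reference age 50, and θ_g the per-year multiplicative trend.  The
latent subtype of a carrier case is drawn ∝ π_s·OR_{g,s}·θ_g^(a−50).
This construction makes the empirical per-subtype case-control odds ratio
converge exactly to OR_{g,s}(a) — the property every parameter-recovery
test exploits.  Markers are then drawn conditional on the latent subtype
(the inverse of the classification rules), so classification on fully
observed markers recovers the latent truth with probability 1, and
missingness is applied last, independently per marker at rates ER 18%,
grade 18%, PR 32%, ERBB2 43% (missing completely at random; an optional
MAR mode shifts the rate with age and country to stress imputation).

Default OR vectors use published point estimates where they exist
(BRCA1 3.26 / 13.5 / 2.27 / 9.85 / 55.32 across the five
subtypes; BRCA2 high-grade 11.53 and TN 10.07; ATM high-grade 4.99; PALB2
high-grade 9.43 and TN 8.05; BARD1 TN 10.05; RAD51C and RAD51D TN 6.19;
age trends 0.96/year for BRCA1 and BRCA2).  Cells without a published
estimate are filled with values consistent with the reported qualitative
pattern
(e.g. CHEK2 associated with all non-TN subtypes but not TN; TP53 with the
ERBB2-positive subtypes) and are **arbitrary placeholders**, as are the
noncarrier subtype proportions (0.55/0.15/0.10/0.05/0.15), the
within-subtype marker distribution (uniform over the compatible cells —
the joint distribution of markers within subtype is not published), the
country set and the size/node/stage marginals.  None of the
parameter-recovery checks depend on the placeholder cells.

What the generator does **not** emulate: tumor morphology, screening
detection mode, family history, between-study heterogeneity in marker
cutoffs, or missingness mechanisms tied to pathology itself.  Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every real-data complication.

## Association models

All models are maximized in-repo by a Newton iteration on the multinomial
logistic log-likelihood (controls as reference outcome), with analytic
gradient and observed-information Hessian, step-halving to force ascent,
and convergence declared at max-norm gradient < 1e-8.  The covariance is
the inverse observed information; confidence intervals are Wald intervals
(symmetric on the log-OR scale), and significance is two-sided at 0.05.
The fitter accepts nonnegative row weights (used by the EM-weighted
analysis) and a linear constraint matrix vec(B) = A·β, which yields the
ordered-trend model (exposure log-OR equal to γ·k at outcome level k) as a
special case.  Binary logistic regression is the K = 1 case.

The standard adjustment set is age (centered at 50 — an arbitrary but
fixed constant; the interaction coefficient is invariant to it) and
country as fixed-effect indicators with the alphabetically first country
as reference.  Age × carrier interaction models add an (age − 50) ×
carrier product; exp of that coefficient is the per-year interaction OR.
Sparse outcome categories (fewer than one carrier case) are dropped with a
warning rather than fitted on an empty cell, matching the practice of
reporting wide CIs rather than applying continuity corrections.  The
case-only heterogeneity test is a likelihood-ratio test, among cases, of
subtype-specific carrier coefficients versus none (df = K − 1).

Rubin's rules pool per-imputation estimates: point = mean, T = W +
(1 + 1/m)B, with the Barnard–Rubin degrees of freedom in the t reference
distribution (infinite complete-data df; B = 0 gives a normal reference).

## Imputation

**Chained equations.**  Markers are initialized from their observed
marginals, then updated in order of increasing missingness for a fixed
number of cycles (default 10; the analysis scripts log marginal drift as a
convergence sanity check).  Binary markers use logistic conditionals,
grade a nominal 3-category multinomial conditional (no proportional-odds
assumption), each with predictors: the other three markers, age, country,
and the per-gene carrier indicators.  Including the analysis-model
exposure among predictors avoids attenuating carrier-subtype
associations.  Imputations are proper: coefficients are drawn from their
asymptotic normal before each predictive draw.  A conditional that fails
to converge falls back to a marginal draw for that sweep with a logged
warning.  Default m = 100; tests and desk-scale scripts use m = 5–20.

**EM.**  The joint distribution θ over the 24 fully crossed marker cells
is estimated from all cases (unstratified by genotype — carrier counts are
far too sparse to stratify θ; the carriers' subtype shift enters through
the downstream weighted regression instead).  The E-step spreads each case
over the cells compatible with its observed fields proportionally to θ;
the M-step renormalizes expected counts; iteration stops when the
observed-data log-likelihood changes by < 1e-8 (trace retained and
verified nondecreasing).  Cell posteriors aggregate through the classifier
to per-case subtype probabilities, which enter the multinomial fit as
fractional row weights.  With every marker missing for every case, θ
stays at its uniform initialization and the model says so in its messages.
Observed values are never altered by either route.

## Absolute risk

Population incidence μ(t) (per 100,000 woman-years, integer ages 20–80)
is split into subtype streams by per-age proportions π_s(t).  Treating
ORs as hazard-ratio approximations (appropriate for a rare outcome) and
holding the carrier frequency fixed across ages (depletion of carriers is
second-order at p < 1%), the noncarrier baseline hazard is constrained
per subtype so the population mixture reproduces the observed incidence:
λ⁰_s(t) = μ(t)π_s(t)/(p·OR_s(t) + 1 − p), carrier hazard λ⁰_s·OR_s(t)
with OR_s(t) = OR_s·θ^(t−50).  Whether the original analysis constrained
the baseline jointly across subtypes or per subtype is not stated in the
available text; the per-subtype constraint is implemented here.

Cumulative risks use the discrete annual product-limit estimator with
competing risk from the other subtypes only (no non-breast-cancer
mortality): rates convert to annual probabilities h = 1 − exp(−rate), an
error is raised if the total annual hazard reaches 1, and the identity
Σ_s F_s(t) + S(t) = 1 holds to 1e-10 at every age.  Halving the age step
changes F_s(80) by well under 1% relative at realistic hazards.

The bundled incidence table is **synthetic** — a smooth logistic ramp from
~5 to ~420 per 100,000 between ages 20 and 80 with constant subtype
proportions, shaped like (but not equal to) breast cancer incidence in a
high-income country — so that nothing needs downloading; real rates can be
supplied as CSV.

## Carrier burden

Under the rare-carrier model the prevalence of carriers among cases of a
given subtype and age is p·OR/(p·OR + 1 − p).  The analytic table
evaluates this with the age-trend OR at the case-weighted mean age of each
group (closer to the group integral than the midpoint when case ages are
non-uniform); the empirical table counts carriers in a (simulated or real)
cohort; both are emitted for cross-validation.  Because carrier states are
mutually exclusive, the combined multi-gene burden is the sum of per-gene
prevalences.

## Problem sizes and numerical choices

Parameter-recovery studies run at 100,000 cases + 100,000 controls with
carrier frequency inflated to 1% (the package's chosen desk scale: large
enough that Monte-Carlo error on a TN OR of 55 is a few percent, small
enough to run in seconds per replicate).  Coverage of pooled CIs is
checked on 200 scaled-down replicates (1,500 per arm, 5% carriers, a
uniform subtype OR of 2.5, m = 5, 3 cycles), and the null calibration of
the heterogeneity test on 1,000 case-only replicates (2,000 cases, equal
ORs across subtypes).  Single global seeds fan out to per-stage and
per-replicate seeds via `numpy.random.SeedSequence`, so every table is
bit-reproducible; identical config + seed yields byte-identical CSVs.

## Known limitations

* The generator's unprinted OR cells, subtype proportions, marker joint
  distribution and incidence curve are documented stand-ins; analyses of
  real data should supply their own.
* Wald CIs and the observed-information covariance can be optimistic with
  very few carrier cases in a category (no profile likelihood, no exact
  logistic regression, no continuity corrections).
* Country enters as fixed effects; no random-effects/meta-analytic
  between-study modeling.
* The risk engine ignores mortality from other causes and second
  primaries; curves are average subtype-specific risks, not individual
  predictions.
* Size/node/stage are generated from fixed marginals and are not imputed
  (analyses involving them are complete-case by design).
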