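"""Simulation studies that exercise the whole stack with known truth.

Each study generates cohorts from the synthetic generator at stated
conditions, runs the corresponding analysis, and reports recovery of the
generating parameters.  These are the routines behind the repository's
headline checks: subtype-OR recovery, age-trend recovery, confidence
interval coverage after imputation, and the null calibration of the
case-only heterogeneity test.
"""

from __future__ import annotations

import numpy as np

from .association import (DesignSpec, fit_age_interaction, fit_multinomial_cc,
                          subtype_heterogeneity_lrt)
from .cohort import generate_cohort
from .config import single_gene_config
from .subtyping import SUBTYPES, classify_dataframe
from .workflows import em_weighted_subtype_ors, mice_pooled_subtype_ors

NO_MISSING = {"er": 0.0, "pr": 0.0, "erbb2": 0.0, "grade": 0.0}
_SMALL_COUNTRIES = {"UK": 0.4, "Germany": 0.35, "Sweden": 0.25}


def child_seed(base: int, index: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2 ** 31))


def or_recovery_study(gene: str, subtype: str, n_per_arm: int = 100_000,
                      n_seeds: int = 10, base_seed: int = 1,
                      carrier_freq: float = 0.01,
                      age_trend: float | None = 1.0) -> dict:
    """Mean fitted subtype OR across seeds at the gene's default OR vector.

    Generates ``n_seeds`` cohorts (no marker missingness), classifies
    subtypes from the fully observed markers, fits the age- and
    country-adjusted case-control multinomial model, and averages the
    log-OR of the requested subtype.
    """
    log_ors = []
    for i in range(n_seeds):
        cfg = single_gene_config(
            gene, carrier_freq=carrier_freq, age_trend=age_trend,
            n_cases=n_per_arm, n_controls=n_per_arm,
            missingness=dict(NO_MISSING), seed=child_seed(base_seed, i))
        cohort = classify_dataframe(generate_cohort(cfg))
        fit = fit_multinomial_cc(cohort, gene)
        log_ors.append(fit.get(subtype, "carrier"))
    log_ors = np.array(log_ors)
    return {
        "mean_or": float(np.exp(log_ors.mean())),
        "log_ors": log_ors.tolist(),
        "mc_se": float(log_ors.std(ddof=1) / np.sqrt(n_seeds)),
        "true_or": float(cfg.subtype_or[gene][subtype]),
        "n_per_arm": n_per_arm, "n_seeds": n_seeds,
    }


def trend_recovery_study(gene: str = "BRCA2", n_per_arm: int = 100_000,
                         n_seeds: int = 10, base_seed: int = 1,
                         carrier_freq: float = 0.01) -> dict:
    """Mean per-year age x carrier interaction OR across seeds.

    The generator applies the gene's default per-year trend multiplicatively
    around the reference age of 50; the case-control logistic model with an
    (age - 50) x carrier product term should recover it.
    """
    logs = []
    for i in range(n_seeds):
        cfg = single_gene_config(
            gene, carrier_freq=carrier_freq,
            n_cases=n_per_arm, n_controls=n_per_arm,
            missingness=dict(NO_MISSING), seed=child_seed(base_seed, i))
        cohort = generate_cohort(cfg)
        fit = fit_age_interaction(cohort, gene)
        logs.append(fit.get("case", "age_c:carrier"))
    logs = np.array(logs)
    return {
        "mean_or": float(np.exp(logs.mean())),
        "mc_se": float(logs.std(ddof=1) / np.sqrt(n_seeds)),
        "true_or": float(cfg.age_trend[gene]),
        "n_per_arm": n_per_arm, "n_seeds": n_seeds,
    }


def missingness_calibration(n_cases: int = 100_000, seed: int = 1) -> dict:
    """Observed missing fractions of each marker among generated cases."""
    cfg = single_gene_config("BRCA1", n_cases=n_cases, n_controls=0, seed=seed)
    cases = generate_cohort(cfg)
    out = {}
    for m, rate in cfg.missingness.items():
        out[m] = {"target": rate, "observed": float((cases[m] == "").mean())}
    out["n_cases"] = n_cases
    return out


def _scaled_config(seed: int, n_per_arm: int, carrier_freq: float,
                   or_value: float, missingness=None):
    ors = {s: or_value for s in SUBTYPES}
    kwargs = {}
    if missingness is not None:  # default: the generator's study-rate MCAR
        kwargs["missingness"] = dict(missingness)
    return single_gene_config(
        "PALB2", carrier_freq=carrier_freq, subtype_or=ors, age_trend=1.0,
        n_cases=n_per_arm, n_controls=n_per_arm, seed=seed,
        countries=dict(_SMALL_COUNTRIES), **kwargs,
    )


def coverage_study(n_reps: int = 200, base_seed: int = 1,
                   n_per_arm: int = 1500, carrier_freq: float = 0.05,
                   or_value: float = 2.5, m: int = 5, cycles: int = 3,
                   subtype: str = "TN") -> dict:
    """CI coverage of the pooled log-OR under missingness at the study rates.

    Each replicate: generate a scaled-down cohort with a uniform subtype OR,
    apply the generator's default (missing-completely-at-random) marker
    missingness, run chained-equations imputation, fit and pool, and check
    whether the 95% CI covers the generating log-OR.  Also records, per
    replicate, the difference between the pooled log-OR and the log-OR from
    the EM-posterior-weighted regression.
    """
    truth = np.log(or_value)
    covered, diffs = [], []
    design = DesignSpec()
    for i in range(n_reps):
        seed = child_seed(base_seed, 1000 + i)
        cfg = _scaled_config(seed, n_per_arm, carrier_freq, or_value)
        cohort = generate_cohort(cfg)
        _, pooled = mice_pooled_subtype_ors(cohort, "PALB2", m=m,
                                            cycles=cycles, seed=seed,
                                            design=design)
        if subtype not in pooled:
            continue
        est = pooled[subtype]
        covered.append(est.ci[0] <= truth <= est.ci[1])
        em = em_weighted_subtype_ors(cohort, "PALB2", design=design)
        diffs.append(est.point - em.get(subtype, "carrier"))
    covered = np.array(covered, bool)
    diffs = np.array(diffs)
    return {
        "coverage": float(covered.mean()),
        "n_reps": int(covered.size),
        "mice_em_mean_diff": float(diffs.mean()),
        "mice_em_diff_mc_se": float(diffs.std(ddof=1) / np.sqrt(len(diffs))),
        "true_log_or": truth,
    }


def heterogeneity_null_study(n_reps: int = 1000, base_seed: int = 1,
                             n_cases: int = 2000, carrier_freq: float = 0.05,
                             or_value: float = 2.0, alpha: float = 0.05) -> dict:
    """Type-I error of the case-only heterogeneity test under the null.

    With the same OR for every subtype, carrier status is independent of
    subtype among cases, so the likelihood-ratio test should reject at its
    nominal rate.
    """
    rejections = 0
    for i in range(n_reps):
        seed = child_seed(base_seed, 2000 + i)
        cfg = _scaled_config(seed, n_cases, carrier_freq, or_value,
                             missingness=NO_MISSING)
        cfg = cfg.with_(n_cases=n_cases, n_controls=0)
        cases = classify_dataframe(generate_cohort(cfg))
        res = subtype_heterogeneity_lrt(cases, "PALB2",
                                         subtype_col="true_subtype")
        rejections += res["p"] < alpha
    return {"type1_error": rejections / n_reps, "n_reps": n_reps,
            "alpha": alpha}
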