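"""Carrier prevalence among cases by age group and subtype.

Under the rare-carrier case-control model, the proportion of cases of a
given subtype (at a given age) who carry the variant follows from Bayes'
theorem on the odds scale:

    prevalence = p * OR / (p * OR + 1 - p)

where p is the population carrier frequency and OR the subtype- and
age-specific odds ratio.  The analytic mode evaluates this closed form with
the age-trend OR at the case-weighted mean age of the group; the empirical
mode counts carriers among (simulated or real) cases.  Because carrier
states are mutually exclusive across genes, the combined multi-gene burden
is the sum of per-gene prevalences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig
from .subtyping import MISSING, SUBTYPES

DEFAULT_AGE_GROUPS = ((18, 40), (41, 60), (61, 79))


def carrier_prevalence_among_cases(p: float, or_value: float) -> float:
    """Closed-form carrier prevalence among cases: p*OR / (p*OR + 1 - p)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"carrier frequency must be in (0, 1), got {p}")
    if or_value <= 0:
        raise ValueError(f"odds ratio must be > 0, got {or_value}")
    return p * or_value / (p * or_value + 1.0 - p)


def _group_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def _case_weighted_mean_age(config: GeneratorConfig, lo: int, hi: int) -> float:
    """Mean case age within [lo, hi] under the generator's age distribution."""
    a, b = config.age_bounds
    dist = stats.truncnorm((a - config.case_age_mean) / config.case_age_sd,
                           (b - config.case_age_mean) / config.case_age_sd,
                           loc=config.case_age_mean, scale=config.case_age_sd)
    ages = np.arange(lo, hi + 1, dtype=float)
    w = dist.pdf(ages)
    if w.sum() <= 0:
        return (lo + hi) / 2.0
    return float((ages * w).sum() / w.sum())


def analytic_burden_table(config: GeneratorConfig,
                          age_groups=DEFAULT_AGE_GROUPS) -> pd.DataFrame:
    """Expected carrier prevalence among cases from the closed form.

    One row per gene x age group x subtype, plus 'combined' rows summing
    over genes (valid because carriers are mutually exclusive).  Age groups
    must partition the inclusion window [18, 79].
    """
    _check_partition(age_groups, config.age_bounds)
    rows = []
    for lo, hi in age_groups:
        mid = _case_weighted_mean_age(config, lo, hi)
        for s in SUBTYPES:
            combined = 0.0
            for g in config.genes:
                theta = config.age_trend.get(g, 1.0)
                orv = config.subtype_or[g][s] * theta ** (mid - config.ref_age)
                prev = carrier_prevalence_among_cases(config.carrier_freq[g], orv)
                rows.append({"gene": g, "age_group": _group_label(lo, hi),
                             "subtype": s, "prevalence": prev,
                             "n_cases": np.nan, "mode": "analytic"})
                combined += prev
            rows.append({"gene": "combined", "age_group": _group_label(lo, hi),
                         "subtype": s, "prevalence": combined,
                         "n_cases": np.nan, "mode": "analytic"})
    return pd.DataFrame(rows)


def empirical_burden_table(cohort: pd.DataFrame,
                           age_groups=DEFAULT_AGE_GROUPS,
                           subtype_col: str = "true_subtype") -> pd.DataFrame:
    """Observed carrier fraction among cases, by age group and subtype."""
    _check_partition(age_groups, (18, 79))
    cases = cohort[cohort["status"] == "case"]
    genes = sorted(g for g in cases["gene"].unique() if g != MISSING)
    rows = []
    for lo, hi in age_groups:
        grp = cases[(cases["age"] >= lo) & (cases["age"] <= hi)]
        for s in SUBTYPES:
            cell = grp[grp[subtype_col] == s]
            n = len(cell)
            for g in genes:
                prev = float((cell["gene"] == g).mean()) if n else np.nan
                rows.append({"gene": g, "age_group": _group_label(lo, hi),
                             "subtype": s, "prevalence": prev,
                             "n_cases": n, "mode": "empirical"})
            prev = float((cell["gene"] != MISSING).mean()) if n else np.nan
            rows.append({"gene": "combined", "age_group": _group_label(lo, hi),
                         "subtype": s, "prevalence": prev,
                         "n_cases": n, "mode": "empirical"})
    return pd.DataFrame(rows)


def burden_table(config: GeneratorConfig, cohort: pd.DataFrame | None = None,
                 age_groups=DEFAULT_AGE_GROUPS,
                 subtype_col: str = "true_subtype") -> pd.DataFrame:
    """Analytic table, plus the empirical table when a cohort is supplied."""
    parts = [analytic_burden_table(config, age_groups)]
    if cohort is not None:
        parts.append(empirical_burden_table(cohort, age_groups, subtype_col))
    return pd.concat(parts, ignore_index=True)


def _check_partition(age_groups, bounds):
    lo, hi = bounds
    expect = lo
    for glo, ghi in age_groups:
        if glo != expect or ghi < glo:
            raise ValueError(f"age groups must partition [{lo}, {hi}]")
        expect = ghi + 1
    if expect != hi + 1:
        raise ValueError(f"age groups must partition [{lo}, {hi}]")
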