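"""Gene- and subtype-specific absolute (cumulative) risk under competing
subtype risks.

Population incidence mu(t) (per 100,000 woman-years) is split into subtype
streams by the per-age subtype proportions pi_s(t).  For a variant with
carrier frequency p and subtype-specific odds ratio OR_s(t) (treated as a
hazard-ratio approximation, standard for rare outcomes), the noncarrier
baseline hazard is constrained so that the population mixture reproduces
the observed incidence exactly:

    lambda0_s(t) = mu(t) * pi_s(t) / (p * OR_s(t) + 1 - p)
    lambda_carrier_s(t) = lambda0_s(t) * OR_s(t)

Cumulative risks use the discrete product-limit estimator on integer ages,
with the competing risk of developing a different subtype first (no other
causes of death):

    S(t) = prod_{u<t} (1 - sum_s h_s(u)),   F_s(T) = sum_{t<T} h_s(t) S(t)

so that sum_s F_s(T) + S(T) = 1 at every age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subtyping import SUBTYPES


@dataclass
class IncidenceModel:
    """Age-indexed population incidence plus subtype proportions.

    ``rate`` is per 100,000 woman-years at each integer age; ``subtype_props``
    is an (n_ages, 5) array whose rows sum to 1.
    """

    ages: np.ndarray
    rate: np.ndarray
    subtype_props: np.ndarray

    def validate(self) -> "IncidenceModel":
        if np.any(self.rate < 0):
            raise ValueError("incidence rates must be nonnegative")
        if self.subtype_props.shape != (len(self.ages), len(SUBTYPES)):
            raise ValueError("subtype_props must be (n_ages, 5)")
        if np.any(np.abs(self.subtype_props.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("subtype proportions must sum to 1 at every age")
        return self

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceModel":
        props = df[[f"prop_{s}" for s in SUBTYPES]].to_numpy(float)
        return cls(ages=df["age"].to_numpy(int),
                   rate=df["rate_per_100000"].to_numpy(float),
                   subtype_props=props).validate()

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"age": self.ages, "rate_per_100000": self.rate})
        for j, s in enumerate(SUBTYPES):
            out[f"prop_{s}"] = self.subtype_props[:, j]
        return out


def synthetic_incidence(ages=None) -> IncidenceModel:
    """A smooth synthetic incidence curve for no-download testing.

    NOT real national rates: a logistic ramp from ~5 to ~420 per 100,000
    woman-years between ages 20 and 80, qualitatively shaped like breast
    cancer incidence in a high-income country, with constant subtype
    proportions.  Real rates can be supplied via CSV instead.
    """
    ages = np.arange(20, 81) if ages is None else np.asarray(ages, int)
    rate = 430.0 / (1.0 + np.exp(-(ages - 58.0) / 9.0))
    props = np.tile([0.55, 0.15, 0.10, 0.05, 0.15], (len(ages), 1))
    return IncidenceModel(ages=ages, rate=rate, subtype_props=props).validate()


def constrained_baseline_hazard(incidence: IncidenceModel, p: float,
                                or_fn) -> tuple:
    """Noncarrier and carrier hazards constrained to the population mixture.

    ``or_fn(subtype, age) -> OR`` gives the subtype- and age-specific odds
    ratio.  Returns ``(baseline, carrier)`` arrays of shape (n_ages, 5), in
    events per woman-year.  The mixture ``p*carrier + (1-p)*baseline``
    reproduces ``mu(t) * pi_s(t)`` exactly.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"carrier frequency must be in (0, 1), got {p}")
    mu = incidence.rate / 1e5
    baseline = np.empty_like(incidence.subtype_props)
    carrier = np.empty_like(baseline)
    for j, s in enumerate(SUBTYPES):
        ors = np.array([or_fn(s, a) for a in incidence.ages], float)
        if np.any(ors <= 0):
            raise ValueError("odds ratios must be > 0")
        baseline[:, j] = mu * incidence.subtype_props[:, j] / (p * ors + 1.0 - p)
        carrier[:, j] = baseline[:, j] * ors
    return baseline, carrier


def cumulative_subtype_risks(hazards: np.ndarray, ages: np.ndarray) -> pd.DataFrame:
    """Discrete product-limit cumulative risks under competing subtypes.

    ``hazards`` is (n_ages, 5) in events per woman-year; rates are converted
    to annual probabilities ``h = 1 - exp(-rate)``.  Returns a DataFrame with
    columns subtype, age, hazard, cum_risk, survival, where ``cum_risk`` at
    age t is the probability of developing that subtype first by the end of
    age t, and ``survival`` is the probability of no breast cancer of any
    subtype.  Conservation: sum_s F_s + S = 1 at every age.
    """
    h = 1.0 - np.exp(-np.asarray(hazards, float))
    total = h.sum(axis=1)
    if np.any(total >= 1.0):
        bad = int(np.asarray(ages)[total >= 1.0][0])
        raise ValueError(f"total annual hazard >= 1 at age {bad}; "
                         "annual discretization invalid")
    n, k = h.shape
    surv_before = np.concatenate([[1.0], np.cumprod(1.0 - total)])  # S at start of age
    F = np.cumsum(h * surv_before[:-1, None], axis=0)
    rows = []
    for j, s in enumerate(SUBTYPES):
        rows.append(pd.DataFrame({
            "subtype": s, "age": ages, "hazard": h[:, j],
            "cum_risk": F[:, j], "survival": surv_before[1:],
        }))
    return pd.concat(rows, ignore_index=True)


def gene_risk_curves(incidence: IncidenceModel, p: float, or_table: dict,
                     theta: float = 1.0, ref_age: float = 50.0,
                     gene: str = "") -> pd.DataFrame:
    """Carrier cumulative risk curves for one gene.

    ``or_table`` maps subtype -> OR at ``ref_age``; the per-year trend
    ``theta`` acts multiplicatively: OR_s(t) = OR_s * theta**(t - ref_age).
    Returns the long-format curve table (gene, subtype, age, hazard,
    cum_risk, survival).
    """
    incidence.validate()

    def or_fn(s, a):
        return or_table[s] * theta ** (a - ref_age)

    _, carrier = constrained_baseline_hazard(incidence, p, or_fn)
    out = cumulative_subtype_risks(carrier, incidence.ages)
    out.insert(0, "gene", gene)
    return out


def population_risk_curves(incidence: IncidenceModel) -> pd.DataFrame:
    """Population (average-woman) cumulative subtype risks, for reference."""
    hazards = (incidence.rate / 1e5)[:, None] * incidence.subtype_props
    out = cumulative_subtype_risks(hazards, incidence.ages)
    out.insert(0, "gene", "population")
    return out
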