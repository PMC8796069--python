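"""Regression machinery: closed forms, oracles, pooling, heterogeneity."""

import numpy as np
import pytest
from scipy import stats

from subtyperisk.association import (DesignSpec, fit_age_interaction,
                                     fit_logistic, fit_multinomial,
                                     fit_multinomial_cc, fit_ordered_trend,
                                     rubin_pool, subtype_heterogeneity_lrt,
                                     trend_constraint)
from subtyperisk.cohort import generate_cohort
from subtyperisk.config import single_gene_config
from subtyperisk.subtyping import SUBTYPES, classify_dataframe

from conftest import NO_MISSING, THREE_COUNTRIES, table_to_rows


def test_saturated_multinomial_matches_closed_form():
    """Intercept+exposure model on a 3-outcome table is saturated, so the
    MLE equals the empirical odds ratios (10/50)/(10/100)=2, (2/50)/(10/100)=0.4."""
    X, y = table_to_rows({
        (0, 0): 100, (1, 0): 10,   # controls: noncarrier, carrier
        (0, 1): 50, (1, 1): 10,    # outcome A
        (0, 2): 50, (1, 2): 2,     # outcome B
    })
    fit = fit_multinomial(X, y, K=2, term_names=["intercept", "carrier"],
                          categories=["A", "B"])
    assert np.exp(fit.get("A", "carrier")) == pytest.approx(2.0, abs=1e-6)
    assert np.exp(fit.get("B", "carrier")) == pytest.approx(0.4, abs=1e-6)


def test_logistic_2x2_closed_form_and_multinomial_consistency():
    X, y = table_to_rows({(1, 1): 10, (0, 1): 90, (1, 0): 5, (0, 0): 95})
    fit = fit_logistic(X, y, term_names=["intercept", "carrier"])
    assert np.exp(fit.get("case", "carrier")) == pytest.approx(
        (10 * 95) / (90 * 5), rel=1e-8)
    # K=1 multinomial is the same model
    mfit = fit_multinomial(X, y, K=1, term_names=["intercept", "carrier"],
                           categories=["case"])
    assert fit.coef == pytest.approx(mfit.coef, abs=1e-8)
    assert fit.loglik == pytest.approx(mfit.loglik, abs=1e-8)


def test_logistic_requires_outcome_variation():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(ValueError, match="variation"):
        fit_logistic(X, np.ones(10, int))


def test_independent_exposure_gives_null_ors():
    """Exposure split identically across outcomes -> all log-ORs exactly 0."""
    X, y = table_to_rows({
        (0, 0): 200, (1, 0): 20,
        (0, 1): 100, (1, 1): 10,
        (0, 2): 50, (1, 2): 5,
    })
    fit = fit_multinomial(X, y, K=2, term_names=["intercept", "carrier"])
    assert np.abs(fit.coef[:, 1]) == pytest.approx(0.0, abs=1e-6)


def _grid_search_logistic(X, y, span=4.0, points=41, refinements=6):
    """Brute-force 2-parameter logistic MLE on an iteratively refined grid."""
    def nll(b0, b1):
        eta = b0 + b1 * X[:, 1]
        return -(y * eta - np.logaddexp(0.0, eta)).sum()

    c0, c1, width = 0.0, 0.0, span
    for _ in range(refinements):
        g0 = np.linspace(c0 - width, c0 + width, points)
        g1 = np.linspace(c1 - width, c1 + width, points)
        vals = np.array([[nll(a, b) for b in g1] for a in g0])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        c0, c1 = g0[i], g1[j]
        width = 2 * width / (points - 1)
    return c0, c1


def test_newton_agrees_with_grid_search_oracle():
    rng = np.random.default_rng(12)
    x = rng.integers(0, 2, size=60).astype(float)
    eta = -0.4 + 0.9 * x
    y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(int)
    X = np.column_stack([np.ones(60), x])
    fit = fit_logistic(X, y, term_names=["intercept", "x"])
    b0, b1 = _grid_search_logistic(X, y)
    assert fit.coef[0, 0] == pytest.approx(b0, abs=1e-4)
    assert fit.coef[0, 1] == pytest.approx(b1, abs=1e-4)


def test_newton_agrees_with_statsmodels_on_simulated_cohort():
    """Independent cross-check of the multinomial fit against statsmodels."""
    sm = pytest.importorskip("statsmodels.api")
    cfg = single_gene_config("BRCA2", carrier_freq=0.05, age_trend=1.0,
                             n_cases=1500, n_controls=1500, seed=9,
                             countries={"UK": 0.6, "Germany": 0.4},
                             missingness=dict(NO_MISSING))
    df = classify_dataframe(generate_cohort(cfg))
    fit = fit_multinomial_cc(df, "BRCA2")
    # rebuild the identical design for statsmodels
    sub = df[(df["status"] == "control")
             | df["intrinsic_subtype"].isin(SUBTYPES)]
    y = np.zeros(len(sub), int)
    for k, s in enumerate(SUBTYPES):
        y[(sub["intrinsic_subtype"] == s).to_numpy()] = k + 1
    X = np.column_stack([
        np.ones(len(sub)),
        (sub["gene"] == "BRCA2").to_numpy(float),
        sub["age"].to_numpy(float) - 50.0,
        (sub["country"] == "UK").to_numpy(float),
    ])
    ref = sm.MNLogit(y, X).fit(disp=0, maxiter=200, method="newton")
    assert fit.coef == pytest.approx(ref.params.T, abs=1e-5)


def test_ordered_trend_recovers_constructed_linearity():
    """Saturated ORs exp(0.3k) satisfy the trend constraint, so the
    constrained MLE returns gamma = 0.3 exactly."""
    base_odds = 0.1  # carrier odds among controls
    rows, weights = [], []
    for k in range(4):  # control + 3 ordered levels
        n_nc = 1000.0 if k == 0 else 500.0
        n_c = n_nc * base_odds * (np.exp(0.3 * k) if k else 1.0)
        rows += [[1.0, 0.0], [1.0, 1.0]]
        weights += [n_nc, n_c]
    X = np.array(rows * 1)
    y = np.repeat(np.arange(4), 2)
    # feed through the DataFrame-free core: constraint on the carrier column
    A = trend_constraint(K=3, p=2, exposure_index=1)
    fit = fit_multinomial(X, y, K=3, weights=np.array(weights), constraint=A,
                          term_names=["intercept", "carrier"],
                          categories=["L1", "L2", "L3"])
    gamma = fit.get("L1", "carrier")
    assert gamma == pytest.approx(0.3, abs=1e-4)
    for k, cat in enumerate(["L1", "L2", "L3"], start=1):
        assert fit.get(cat, "carrier") == pytest.approx(gamma * k, abs=1e-10)
    # likelihood-ratio statistic vs the saturated model is nonnegative
    sat = fit_multinomial(X, y, K=3, weights=np.array(weights),
                          term_names=["intercept", "carrier"])
    assert 2 * (sat.loglik - fit.loglik) >= -1e-8


def test_ordered_trend_null_exposure():
    X, y = table_to_rows({(0, 0): 300, (1, 0): 30,
                          (0, 1): 100, (1, 1): 10,
                          (0, 2): 80, (1, 2): 8,
                          (0, 3): 50, (1, 3): 5})
    A = trend_constraint(K=3, p=2, exposure_index=1)
    fit = fit_multinomial(X, y, K=3, constraint=A,
                          term_names=["intercept", "carrier"],
                          categories=["L1", "L2", "L3"])
    assert fit.get("L1", "carrier") == pytest.approx(0.0, abs=1e-6)


def test_ordered_trend_dataframe_wrapper(complete_cohort):
    df = classify_dataframe(complete_cohort)
    gamma, se, fit = fit_ordered_trend(
        df[df["size_cat"] != ""], "BRCA2", "size_cat",
        levels=["<2cm", "2-5cm", ">5cm"])
    assert np.isfinite(gamma) and se > 0
    assert fit.converged


def test_case_only_or_ratio_identity(complete_cohort):
    """Case-only OR ratio between two subtypes equals the ratio of the two
    case-control ORs (same data, no covariates)."""
    df = classify_dataframe(complete_cohort)
    design = DesignSpec(covariates=())
    cc = fit_multinomial_cc(df, "BRCA2", design=design)
    cases = df[df["status"] == "case"]
    sub = cases[cases["intrinsic_subtype"].isin(SUBTYPES)]
    y = np.zeros(len(sub), int)
    for k, s in enumerate(SUBTYPES[1:]):
        y[(sub["intrinsic_subtype"] == s).to_numpy()] = k + 1
    X = np.column_stack([np.ones(len(sub)),
                         (sub["gene"] == "BRCA2").to_numpy(float)])
    co = fit_multinomial(X, y, K=4, term_names=["intercept", "carrier"],
                         categories=SUBTYPES[1:])
    for s in SUBTYPES[1:]:
        case_only_ratio = co.get(s, "carrier")
        cc_ratio = cc.get(s, "carrier") - cc.get(SUBTYPES[0], "carrier")
        assert case_only_ratio == pytest.approx(cc_ratio, abs=1e-6)


def test_heterogeneity_statistic_zero_when_proportional():
    """Carriers spread across subtypes exactly proportionally to
    noncarriers -> LRT statistic ~ 0."""
    import pandas as pd
    rows = []
    for s, n in zip(SUBTYPES, (500, 200, 100, 50, 150)):
        for carrier, cnt in (("", n), ("PALB2", n // 10)):
            rows.append(pd.DataFrame({
                "status": "case", "age": 55, "country": "UK",
                "gene": carrier, "intrinsic_subtype": s,
            }, index=range(cnt)))
    cases = pd.concat(rows, ignore_index=True)
    res = subtype_heterogeneity_lrt(cases, "PALB2",
                                     design=DesignSpec(covariates=()))
    assert res["df"] == 4
    assert res["statistic"] == pytest.approx(0.0, abs=1e-6)
    assert res["p"] > 0.999


def test_heterogeneity_requires_carriers(complete_cohort):
    df = classify_dataframe(complete_cohort)
    with pytest.raises(ValueError, match="carriers"):
        subtype_heterogeneity_lrt(df[df["status"] == "case"], "RAD51C")


def test_age_interaction_null_and_centering_invariance():
    cfg = single_gene_config("PALB2", carrier_freq=0.02, age_trend=1.0,
                             n_cases=20000, n_controls=20000, seed=21,
                             countries=dict(THREE_COUNTRIES),
                             missingness=dict(NO_MISSING))
    df = generate_cohort(cfg)
    fit = fit_age_interaction(df, "PALB2")
    est = fit.get("case", "age_c:carrier")
    se = fit.se("case", "age_c:carrier")
    assert abs(est) < 3 * se  # theta = 1 -> interaction OR = 1
    # the interaction coefficient is invariant to the centering constant
    shifted = fit_age_interaction(df, "PALB2",
                                  design=DesignSpec(age_center=30.0))
    assert shifted.get("case", "age_c:carrier") == pytest.approx(est, abs=1e-6)
    assert shifted.get("case", "carrier") != pytest.approx(
        fit.get("case", "carrier"), abs=1e-3)


def test_rubin_pool_worked_example():
    est = rubin_pool([0.5, 0.7], [0.01, 0.01])
    assert est.point == pytest.approx(0.6)
    assert est.within_var == pytest.approx(0.01)
    assert est.between_var == pytest.approx(0.02)
    assert est.total_var == pytest.approx(0.01 + 1.5 * 0.02)


def test_rubin_pool_degenerate_cases():
    same = rubin_pool([0.3, 0.3, 0.3], [0.04, 0.04, 0.04])
    assert same.between_var == 0.0
    assert same.total_var == same.within_var
    single = rubin_pool([1.2], [0.25])
    assert single.point == 1.2
    assert single.total_var == 0.25
    z = 1.2 / 0.5
    assert single.p == pytest.approx(2 * stats.norm.sf(z))
    with pytest.raises(ValueError):
        rubin_pool([0.1], [0.0])


def test_sparse_category_dropped_with_warning(complete_cohort):
    """A subtype with no carrier cases is dropped, not fitted on an empty cell."""
    df = classify_dataframe(complete_cohort)
    # remove all carrier TN cases
    drop = (df["gene"] == "BRCA2") & (df["intrinsic_subtype"] == "TN")
    df = df[~drop]
    with pytest.warns(UserWarning, match="TN"):
        fit = fit_multinomial_cc(df, "BRCA2")
    assert "TN" not in fit.categories
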