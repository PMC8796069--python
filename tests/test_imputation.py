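"""Chained-equations and EM imputation of the pathology markers."""

import numpy as np
import pandas as pd
import pytest

from subtyperisk.association import fit_logistic
from subtyperisk.cohort import generate_cohort
from subtyperisk.config import single_gene_config
from subtyperisk.imputation import (MARKERS, em_fit,
                                    em_subtype_probabilities,
                                    em_subtype_weight_matrix, mice_impute)
from subtyperisk.subtyping import CELLS, MISSING, SUBTYPES

from conftest import NO_MISSING, THREE_COUNTRIES


def _cases(cohort):
    return cohort[cohort["status"] == "case"].reset_index(drop=True)


def test_mice_identity_without_missingness(complete_cohort):
    cases = _cases(complete_cohort)
    imp = mice_impute(cases, m=3, cycles=2, seed=0)
    assert imp.m == 3
    for ds in imp.datasets:
        pd.testing.assert_frame_equal(ds, cases)


def test_mice_never_alters_observed_values(small_cohort):
    cases = _cases(small_cohort)
    imp = mice_impute(cases, m=2, cycles=2, seed=1)
    for ds in imp.datasets:
        for m in MARKERS:
            obs = cases[m] != MISSING
            assert (ds.loc[obs, m] == cases.loc[obs, m]).all()
            assert (ds[m] != MISSING).all()


def test_mice_single_missing_erbb2_matches_logistic_conditional():
    """One case missing only ERBB2: across m=200 imputations the positive
    rate approximates the logistic conditional fitted on complete cases."""
    cfg = single_gene_config("BRCA2", carrier_freq=0.05, age_trend=1.0,
                             n_cases=800, n_controls=0, seed=13,
                             countries=dict(THREE_COUNTRIES),
                             missingness=dict(NO_MISSING))
    cases = _cases(generate_cohort(cfg))
    target = 0
    cases.loc[target, "erbb2"] = MISSING

    # oracle: refit the logistic conditional on the complete cases
    complete = cases.drop(index=target)
    levels = sorted(cases["country"].unique())[1:]
    X = np.column_stack([
        np.ones(len(complete)),
        (complete["er"] == "pos").to_numpy(float),
        (complete["pr"] == "pos").to_numpy(float),
        (complete["grade"] == "2").to_numpy(float),
        (complete["grade"] == "3").to_numpy(float),
        complete["age"].to_numpy(float) - 50.0,
    ] + [(complete["country"] == lev).to_numpy(float) for lev in levels]
      + [(complete["gene"] == "BRCA2").to_numpy(float)])
    y = (complete["erbb2"] == "pos").to_numpy(int)
    fit = fit_logistic(X, y)
    row = cases.loc[target]
    x0 = np.array([1.0, row["er"] == "pos", row["pr"] == "pos",
                   row["grade"] == "2", row["grade"] == "3",
                   row["age"] - 50.0]
                  + [row["country"] == lev for lev in levels]
                  + [row["gene"] == "BRCA2"], float)
    p_oracle = 1.0 / (1.0 + np.exp(-(x0 @ fit.coef[0])))

    imp = mice_impute(cases, m=200, cycles=1, seed=7)
    rate = np.mean([ds.loc[target, "erbb2"] == "pos" for ds in imp.datasets])
    # binomial noise over 200 draws plus parameter-draw spread
    assert abs(rate - p_oracle) < 0.12


def test_em_complete_data_equals_empirical_frequencies(complete_cohort):
    cases = _cases(complete_cohort)
    model = em_fit(cases)
    key = list(zip(cases["er"], cases["pr"], cases["erbb2"], cases["grade"]))
    emp = np.array([key.count(c) for c in model.cells], float) / len(cases)
    assert model.theta == pytest.approx(emp, abs=1e-12)


def test_em_loglik_trace_nondecreasing_over_random_instances():
    for s in range(100):
        rng = np.random.default_rng(s)
        n = 150
        cells = [CELLS[i] for i in rng.integers(0, len(CELLS), n)]
        df = pd.DataFrame(cells, columns=MARKERS)
        df["status"] = "case"
        # random masking
        for m in MARKERS:
            df.loc[rng.random(n) < 0.4, m] = MISSING
        model = em_fit(df, tol=1e-10, max_iter=300)
        diffs = np.diff(model.loglik_trace)
        assert (diffs >= -1e-9).all()


def test_em_uninformative_case_posterior_equals_theta(small_cohort):
    cases = _cases(small_cohort).copy()
    cases.loc[0, MARKERS] = MISSING
    model = em_fit(cases)
    post = model.posterior(MISSING, MISSING, MISSING, MISSING)
    assert post == pytest.approx(model.theta, abs=1e-12)


def test_em_posterior_zero_on_incompatible_cells(small_cohort):
    model = em_fit(_cases(small_cohort))
    post = model.posterior("pos", MISSING, "neg", MISSING)
    for p, cell in zip(post, model.cells):
        if cell[0] != "pos" or cell[2] != "neg":
            assert p == 0.0
    assert post.sum() == pytest.approx(1.0, abs=1e-12)


def test_em_subtype_probabilities_observed_and_missing(small_cohort):
    model = em_fit(_cases(small_cohort))
    tn = model.subtype_probabilities("neg", "neg", "neg", "3")
    assert tn["TN"] == pytest.approx(1.0)
    allmiss = model.subtype_probabilities(MISSING, MISSING, MISSING, MISSING)
    # equals theta aggregated through the classifier
    from subtyperisk.subtyping import classify
    agg = {s: 0.0 for s in SUBTYPES}
    for t, cell in zip(model.theta, model.cells):
        agg[classify(*cell)] += t
    for s in SUBTYPES:
        assert allmiss[s] == pytest.approx(agg[s], abs=1e-12)
    assert sum(allmiss.values()) == pytest.approx(1.0)


def test_em_expected_subtype_counts_match_complete_data():
    """Aggregate EM-expected subtype counts on MCAR-masked data stay close
    to the complete-data subtype counts (the oracle)."""
    cfg = single_gene_config("BRCA2", carrier_freq=0.05, age_trend=1.0,
                             n_cases=4000, n_controls=0, seed=17,
                             countries=dict(THREE_COUNTRIES),
                             missingness=dict(NO_MISSING))
    complete = _cases(generate_cohort(cfg))
    masked = complete.copy()
    rng = np.random.default_rng(3)
    from subtyperisk.cohort import apply_missingness
    masked = apply_missingness(masked, {"er": 0.18, "grade": 0.18,
                                        "pr": 0.32, "erbb2": 0.43}, rng)
    model = em_fit(masked)
    W = em_subtype_weight_matrix(model, masked)
    expected = W.sum(axis=0)
    truth = np.array([(complete["true_subtype"] == s).sum() for s in SUBTYPES])
    # the difference has SD at most sqrt(sum w(1-w)) per subtype
    sd = np.sqrt((W * (1 - W)).sum(axis=0)) + 1.0
    assert (np.abs(expected - truth) < 5 * sd).all()


def test_em_rejects_empty_input():
    with pytest.raises(ValueError):
        em_fit(pd.DataFrame(columns=MARKERS + ["status"]))


def test_em_all_missing_flags_initialization(small_cohort):
    cases = _cases(small_cohort).head(50).copy()
    cases[MARKERS] = MISSING
    model = em_fit(cases)
    assert any("initialization" in m for m in model.messages)
    assert model.theta == pytest.approx(np.full(24, 1 / 24), abs=1e-12)


def test_em_subtype_probabilities_row_accessor(small_cohort):
    model = em_fit(_cases(small_cohort))
    row = {"er": "neg", "pr": "neg", "erbb2": "neg", "grade": "1"}
    probs = em_subtype_probabilities(model, row)
    assert probs["TN"] == pytest.approx(1.0)
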