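"""Imputation of missing pathology markers among cases.

Two routes, mirroring each other's assumptions:

* :func:`mice_impute` — Multiple Imputation by Chained Equations.  Each
  incomplete marker is regressed on the other markers plus age, country and
  the per-gene carrier indicators (binary markers via logistic conditionals,
  grade via a 3-category multinomial conditional); missing entries are
  redrawn from the fitted predictive distribution with the coefficients
  themselves drawn from their estimated sampling distribution, so that the
  imputations are "proper" and Rubin's rules apply downstream.  m
  independent chains give m completed data sets.

* :func:`em_fit` — maximum likelihood for the joint distribution of the 24
  fully crossed (ER, PR, ERBB2, grade) cells from partially observed data
  by expectation-maximization, yielding per-case posterior probabilities
  over compatible cells (and, through the classifier, over subtypes).

Observed values are never altered by either route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import subtyping
from .association import ConvergenceError, fit_logistic, fit_multinomial
from .subtyping import CELLS, MISSING, SUBTYPES, classify, compatible_cells

log = logging.getLogger(__name__)

MARKERS = ["er", "pr", "erbb2", "grade"]
_BINARY = {"er", "pr", "erbb2"}


# ----------------------------------------------------------------------
# MICE
# ----------------------------------------------------------------------

@dataclass
class ImputationSet:
    """m completed case tables; observed marker values are untouched."""

    m: int
    datasets: list              # list of DataFrames (cases, no missing markers)
    seed: int
    cycles: int
    predictors: tuple = ()


def _predictor_matrix(cases: pd.DataFrame, target: str, genes: list):
    """Design for one conditional model: other markers + age + country + genes."""
    n = len(cases)
    cols, names = [np.ones(n)], ["intercept"]
    for m in MARKERS:
        if m == target:
            continue
        if m in _BINARY:
            cols.append((cases[m] == "pos").to_numpy(float))
            names.append(f"{m}_pos")
        else:
            for g in ("2", "3"):
                cols.append((cases["grade"] == g).to_numpy(float))
                names.append(f"grade_{g}")
    cols.append(cases["age"].to_numpy(float) - 50.0)
    names.append("age_c")
    for lev in sorted(cases["country"].unique())[1:]:
        cols.append((cases["country"] == lev).to_numpy(float))
        names.append(f"country[{lev}]")
    for g in genes:
        cols.append((cases["gene"] == g).to_numpy(float))
        names.append(f"carrier[{g}]")
    return np.column_stack(cols), names


def _draw_coefs(coef_flat, cov, rng):
    """One draw from the asymptotic normal of the fitted coefficients."""
    cov = (cov + cov.T) / 2.0
    try:
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return coef_flat + L @ rng.standard_normal(len(coef_flat))


def _impute_variable(cases, target, observed_mask, genes, rng):
    """One chained-equations update of ``target`` (in place)."""
    X, _ = _predictor_matrix(cases, target, genes)
    miss = ~observed_mask
    if not miss.any():
        return
    if target in _BINARY:
        y = (cases.loc[observed_mask, target] == "pos").to_numpy(int)
        try:
            fit = fit_logistic(X[observed_mask], y)
            beta = _draw_coefs(fit.coef.reshape(-1), fit.cov, rng)
            eta = X[miss] @ beta
            p = expit(eta)
            draws = np.where(rng.random(miss.sum()) < p, "pos", "neg")
        except (ConvergenceError, ValueError) as exc:
            log.warning("conditional for %s failed (%s); marginal draw", target, exc)
            p = float((cases.loc[observed_mask, target] == "pos").mean())
            draws = np.where(rng.random(miss.sum()) < p, "pos", "neg")
        cases.loc[miss, target] = draws
    else:  # grade: 3-category multinomial, reference grade 1
        yobs = cases.loc[observed_mask, "grade"].to_numpy()
        y = np.zeros(observed_mask.sum(), int)
        y[yobs == "2"] = 1
        y[yobs == "3"] = 2
        try:
            fit = fit_multinomial(X[observed_mask], y, K=2)
            beta = _draw_coefs(fit.coef.reshape(-1), fit.cov, rng).reshape(2, -1)
            eta = X[miss] @ beta.T
            eta = np.concatenate([np.zeros((miss.sum(), 1)), eta], axis=1)
            eta -= eta.max(axis=1, keepdims=True)
            p = np.exp(eta)
            p /= p.sum(axis=1, keepdims=True)
            idx = (rng.random((miss.sum(), 1)) > np.cumsum(p, axis=1)).sum(axis=1)
        except (ConvergenceError, ValueError) as exc:
            log.warning("conditional for grade failed (%s); marginal draw", exc)
            counts = np.array([(yobs == g).sum() for g in ("1", "2", "3")], float)
            idx = rng.choice(3, size=miss.sum(), p=counts / counts.sum())
        cases.loc[miss, "grade"] = np.array(["1", "2", "3"], object)[idx]


def mice_impute(cases: pd.DataFrame, m: int = 100, cycles: int = 10,
                seed: int = 0) -> ImputationSet:
    """Multiple Imputation by Chained Equations for the marker columns.

    Returns m completed copies of ``cases``.  Variables are visited in
    order of increasing missingness; the first fill draws from the observed
    marginal of each marker.  With zero missingness all m data sets equal
    the input.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    cases = cases.reset_index(drop=True)
    observed = {t: (cases[t] != MISSING).to_numpy() for t in MARKERS}
    order = sorted(MARKERS, key=lambda t: observed[t].sum(), reverse=True)
    genes = sorted(g for g in cases["gene"].unique() if g != MISSING)
    children = np.random.SeedSequence(seed).spawn(m)
    datasets = []
    for chain in range(m):
        rng = np.random.default_rng(children[chain])
        work = cases.copy()
        # initial fill from observed marginals
        for t in MARKERS:
            miss = ~observed[t]
            if not miss.any():
                continue
            obs_vals = work.loc[observed[t], t].to_numpy()
            if obs_vals.size == 0:
                raise ValueError(f"marker {t!r} has no observed values")
            work.loc[miss, t] = rng.choice(obs_vals, size=miss.sum())
        if any((~observed[t]).any() for t in MARKERS):
            for _ in range(cycles):
                for t in order:
                    if (~observed[t]).any():
                        _impute_variable(work, t, observed[t], genes, rng)
        datasets.append(work)
    return ImputationSet(m=m, datasets=datasets, seed=seed, cycles=cycles,
                         predictors=("markers", "age", "country", "carriers"))


# ----------------------------------------------------------------------
# EM over the 24-cell joint distribution
# ----------------------------------------------------------------------

@dataclass
class JointCellModel:
    """ML estimate of the joint (ER, PR, ERBB2, grade) cell probabilities."""

    cells: list
    theta: np.ndarray           # (24,) probabilities, sums to 1
    loglik_trace: list
    converged: bool
    messages: list = field(default_factory=list)

    def posterior(self, er, pr, erbb2, grade) -> np.ndarray:
        """Posterior over the 24 cells given (possibly partial) markers."""
        idx = [self.cells.index(c) for c in compatible_cells(er, pr, erbb2, grade)]
        out = np.zeros(len(self.cells))
        mass = self.theta[idx].sum()
        if mass <= 0:
            out[idx] = 1.0 / len(idx)
        else:
            out[idx] = self.theta[idx] / mass
        return out

    def subtype_probabilities(self, er, pr, erbb2, grade) -> dict:
        """Posterior subtype probabilities: cell posterior through classify."""
        post = self.posterior(er, pr, erbb2, grade)
        out = {s: 0.0 for s in SUBTYPES}
        for p, cell in zip(post, self.cells):
            out[classify(*cell)] += float(p)
        return out


def _pattern_groups(cases: pd.DataFrame):
    """Group cases by observed-marker pattern; returns {key: (count, cell_idx)}."""
    cell_index = {c: i for i, c in enumerate(CELLS)}
    markers = cases[MARKERS].astype(str)
    key = (markers["er"] + "|" + markers["pr"] + "|" + markers["erbb2"]
           + "|" + markers["grade"])
    groups = {}
    for k, cnt in key.value_counts().items():
        er, pr, erbb2, grade = k.split("|", 3)
        idx = np.array([cell_index[c] for c in compatible_cells(er, pr, erbb2, grade)])
        groups[k] = (int(cnt), idx)
    return groups


def em_fit(cases: pd.DataFrame, tol: float = 1e-8, max_iter: int = 1000) -> JointCellModel:
    """EM for the joint cell distribution from partially observed markers.

    E-step distributes each case over the cells compatible with its observed
    fields in proportion to the current theta; the M-step renormalizes the
    expected counts.  The observed-data log-likelihood trace is nondecreasing.
    """
    if len(cases) == 0:
        raise ValueError("em_fit needs at least one case")
    groups = _pattern_groups(cases)
    messages = []
    if all(len(idx) == len(CELLS) for _, idx in groups.values()):
        messages.append("all markers missing for every case; "
                        "theta stays at initialization")
    theta = np.full(len(CELLS), 1.0 / len(CELLS))
    trace = []
    converged = False
    for _ in range(max_iter):
        counts = np.zeros(len(CELLS))
        ll = 0.0
        for cnt, idx in groups.values():
            mass = theta[idx].sum()
            if mass <= 0:
                counts[idx] += cnt / len(idx)
                continue
            counts[idx] += cnt * theta[idx] / mass
            ll += cnt * np.log(mass)
        trace.append(ll)
        theta = counts / counts.sum()
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return JointCellModel(cells=list(CELLS), theta=theta, loglik_trace=trace,
                          converged=converged, messages=messages)


def em_subtype_probabilities(model: JointCellModel, case) -> dict:
    """Subtype probability vector for one case (row or mapping with markers)."""
    return model.subtype_probabilities(case["er"], case["pr"],
                                       case["erbb2"], case["grade"])


def em_subtype_weight_matrix(model: JointCellModel, cases: pd.DataFrame) -> np.ndarray:
    """(n_cases, 5) matrix of posterior subtype probabilities, row order kept."""
    markers = cases[MARKERS].astype(str)
    key = (markers["er"] + "|" + markers["pr"] + "|" + markers["erbb2"]
           + "|" + markers["grade"])
    lut = {}
    for k in key.unique():
        probs = model.subtype_probabilities(*k.split("|", 3))
        lut[k] = np.array([probs[s] for s in SUBTYPES])
    return np.stack([lut[k] for k in key])
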