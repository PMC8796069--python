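"""Case-control and case-only regression models, implemented from first
principles.

The workhorse is a Newton-type maximizer of the multinomial logistic
log-likelihood with controls (or a designated reference level) as the
baseline outcome category, supporting row weights and linear parameter
constraints.  Binary logistic regression is the K=1 special case; the
ordered-trend model (log OR linear in the outcome level) is a linear
constraint on the exposure coefficients.  Confidence intervals are Wald
intervals from the observed information.  Estimates from multiply imputed
data sets are combined with Rubin's rules using the Barnard-Rubin degrees
of freedom.

Everything here operates either on plain design matrices (``fit_multinomial``)
or on cohort DataFrames via small wrappers that build the standard design:
intercept, per-gene carrier indicator, age centered at 50 and country
fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .subtyping import MISSING, SUBTYPES

AGE_CENTER = 50.0


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the gradient tolerance."""


@dataclass
class ORFit:
    """A fitted model: log-ORs per outcome category with Wald machinery."""

    categories: list            # case outcome categories (reference excluded)
    terms: list                 # design column names
    coef: np.ndarray            # (K, p) log-odds coefficients
    cov: np.ndarray             # (K*p, K*p) covariance, row-major over (k, j)
    loglik: float
    n_used: int
    converged: bool
    messages: list = field(default_factory=list)

    def se(self, category, term) -> float:
        i = self._index(category, term)
        return float(np.sqrt(self.cov[i, i]))

    def get(self, category, term) -> float:
        k = self.categories.index(category)
        j = self.terms.index(term)
        return float(self.coef[k, j])

    def _index(self, category, term) -> int:
        return self.categories.index(category) * len(self.terms) + self.terms.index(term)

    def or_table(self, term: str = "carrier", label: str = "") -> pd.DataFrame:
        """Tidy OR table for one term: one row per outcome category."""
        rows = []
        for k, cat in enumerate(self.categories):
            est = self.get(cat, term)
            se = self.se(cat, term)
            z = est / se if se > 0 else np.nan
            rows.append({
                "gene": label, "outcome_category": cat,
                "OR": np.exp(est), "ci_low": np.exp(est - 1.959963984540054 * se),
                "ci_high": np.exp(est + 1.959963984540054 * se),
                "p": 2 * stats.norm.sf(abs(z)), "log_or": est, "se": se,
            })
        return pd.DataFrame(rows)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    m: int
    df: float
    ci: tuple
    p: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def _loglik_probs(X, coef, y, w):
    """Log-likelihood and per-row category probabilities (n, K+1)."""
    eta = X @ coef.T                                   # (n, K)
    eta0 = np.concatenate([np.zeros((len(X), 1)), eta], axis=1)
    lse = logsumexp(eta0, axis=1)
    probs = np.exp(eta0 - lse[:, None])
    ll = float(np.sum(w * (eta0[np.arange(len(X)), y] - lse)))
    return ll, probs


def fit_multinomial(X, y, K, weights=None, constraint=None, term_names=None,
                    categories=None, tol=1e-8, max_iter=100):
    """Maximize the multinomial logistic likelihood by Newton iteration.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) integer outcome, 0 = reference category, 1..K = case categories.
    K : number of non-reference categories.
    weights : optional nonnegative row weights (fractional allowed).
    constraint : optional (K*p, q) matrix A such that vec(coef) = A @ beta;
        the default is the unconstrained (saturated over categories) model.
    tol : convergence threshold on the max-norm of the (reduced) gradient.

    Returns an :class:`ORFit`.  Raises :class:`ConvergenceError` (with the
    iteration trace in the message) if the tolerance is not met.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    A = np.eye(K * p) if constraint is None else np.asarray(constraint, float)
    q = A.shape[1]

    # full-rank check on the weighted cross-product
    xtx = X.T @ (w[:, None] * X)
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(q)
    messages: list = []
    ll, probs = _loglik_probs(X, (A @ beta).reshape(K, p), y, w)
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        # gradient and Hessian in the full (K*p) space
        resid = np.stack([(y == k + 1).astype(float) - probs[:, k + 1]
                          for k in range(K)], axis=1)      # (n, K)
        g_full = (X.T @ (w[:, None] * resid)).T.reshape(-1)  # vec over (k, j)
        H_full = np.empty((K * p, K * p))
        for k in range(K):
            for l in range(k, K):
                pk, pl = probs[:, k + 1], probs[:, l + 1]
                wkl = w * (pk * ((k == l) - pl))
                block = -(X.T @ (wkl[:, None] * X))
                H_full[k * p:(k + 1) * p, l * p:(l + 1) * p] = block
                H_full[l * p:(l + 1) * p, k * p:(k + 1) * p] = block
        g = A.T @ g_full
        H = A.T @ H_full @ A
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            messages.append("singular Hessian; ridge added")
            step = np.linalg.solve(-H + 1e-8 * np.eye(q), g)
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, probs_new = _loglik_probs(X, (A @ cand).reshape(K, p), y, w)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, probs = cand, ll_new, probs_new
        trace.append(ll)
    if not converged:
        raise ConvergenceError(
            f"Newton iteration did not converge; log-likelihood trace: {trace}")
    cov_red = np.linalg.inv(-H) if q else np.zeros((0, 0))
    cov_full = A @ cov_red @ A.T
    coef = (A @ beta).reshape(K, p)
    if np.any(np.abs(coef) > 12):
        messages.append("extreme coefficient: possible separation / empty cell")
    term_names = term_names or [f"x{j}" for j in range(p)]
    categories = list(categories) if categories is not None else list(range(1, K + 1))
    return ORFit(categories=categories, terms=list(term_names), coef=coef,
                 cov=cov_full, loglik=ll, n_used=n, converged=converged,
                 messages=messages)


def fit_logistic(X, y, weights=None, term_names=None, tol=1e-8, max_iter=100):
    """Binary logistic regression: the K=1 multinomial special case."""
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has no variation")
    return fit_multinomial(X, y, K=1, weights=weights, term_names=term_names,
                           categories=["case"], tol=tol, max_iter=max_iter)


# ----------------------------------------------------------------------
# DataFrame-level design construction and wrappers
# ----------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Standard adjustment set for the case-control models.

    ``covariates`` may contain ``"age"`` (centered at ``age_center``) and
    ``"country"`` (fixed-effect indicators, reference = first
    alphabetically); ``extras`` adds indicator blocks for e.g. ``size_cat``
    or ``node``; ``age_interaction`` adds an (age - center) x carrier
    product term.
    """

    covariates: tuple = ("age", "country")
    extras: tuple = ()
    age_interaction: bool = False
    age_center: float = AGE_CENTER


def build_design(df: pd.DataFrame, carrier: np.ndarray, design: DesignSpec):
    """Design matrix [intercept, carrier, covariates...] with term names."""
    cols = [np.ones(len(df)), carrier.astype(float)]
    names = ["intercept", "carrier"]
    if "age" in design.covariates:
        age_c = df["age"].to_numpy(float) - design.age_center
        cols.append(age_c)
        names.append("age_c")
    if "country" in design.covariates:
        levels = sorted(df["country"].unique())
        for lev in levels[1:]:
            cols.append((df["country"] == lev).to_numpy(float))
            names.append(f"country[{lev}]")
    for extra in design.extras:
        levels = sorted(v for v in df[extra].unique() if v != MISSING)
        for lev in levels[1:]:
            cols.append((df[extra] == lev).to_numpy(float))
            names.append(f"{extra}[{lev}]")
    if design.age_interaction:
        age_c = df["age"].to_numpy(float) - design.age_center
        cols.append(age_c * carrier.astype(float))
        names.append("age_c:carrier")
    return np.column_stack(cols), names


def _gene_subset(df: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Noncarriers plus carriers of ``gene`` (other-gene carriers excluded)."""
    return df[df["gene"].isin([MISSING, gene])]


def fit_multinomial_cc(df: pd.DataFrame, gene: str,
                       design: DesignSpec | None = None,
                       subtype_col: str = "intrinsic_subtype",
                       categories: list | None = None,
                       weights: np.ndarray | None = None,
                       min_carriers: int = 1) -> ORFit:
    """Case-control multinomial model: subtype (controls reference) ~ carrier.

    Cases with an undetermined or missing subtype are excluded (complete-case
    behaviour); categories with fewer than ``min_carriers`` carrier cases are
    dropped with a warning rather than fitted on an empty cell.
    """
    design = design or DesignSpec()
    categories = list(categories or SUBTYPES)
    if weights is not None:
        weights = np.asarray(weights, float)[
            df["gene"].isin([MISSING, gene]).to_numpy()]
    sub = _gene_subset(df, gene)
    keep = (sub["status"] == "control") | sub[subtype_col].isin(categories)
    if weights is not None:
        weights = weights[keep.to_numpy()]
    sub = sub[keep]
    carrier = (sub["gene"] == gene).to_numpy()
    kept = []
    for cat in categories:
        n_carrier = int((carrier & (sub[subtype_col] == cat).to_numpy()).sum())
        if n_carrier >= min_carriers:
            kept.append(cat)
        else:
            warnings.warn(f"category {cat!r} dropped: {n_carrier} carrier cases")
    drop = (sub["status"] == "case") & ~sub[subtype_col].isin(kept)
    if weights is not None:
        weights = weights[~drop.to_numpy()]
    sub = sub[~drop]
    carrier = (sub["gene"] == gene).to_numpy()
    y = np.zeros(len(sub), int)
    for k, cat in enumerate(kept):
        y[(sub[subtype_col] == cat).to_numpy()] = k + 1
    X, names = build_design(sub, carrier, design)
    return fit_multinomial(X, y, K=len(kept), weights=weights,
                           term_names=names, categories=kept)


def fit_binary_logistic(df: pd.DataFrame, gene: str, outcome: np.ndarray | str,
                        design: DesignSpec | None = None) -> ORFit:
    """Case-control (or any binary endpoint) logistic model for one gene.

    ``outcome`` is a boolean array aligned with ``df`` or the string
    ``"case"`` for plain case-control status.
    """
    design = design or DesignSpec()
    sub = _gene_subset(df, gene)
    if isinstance(outcome, str) and outcome == "case":
        yb = (sub["status"] == "case").to_numpy()
    else:
        yb = np.asarray(outcome, bool)[df["gene"].isin([MISSING, gene]).to_numpy()]
    carrier = (sub["gene"] == gene).to_numpy()
    X, names = build_design(sub, carrier, design)
    fit = fit_logistic(X, yb.astype(int), term_names=names)
    return fit


def fit_age_interaction(df: pd.DataFrame, gene: str,
                        design: DesignSpec | None = None) -> ORFit:
    """Case-control logistic model with an (age - 50) x carrier product term.

    ``exp(coef)`` of the ``age_c:carrier`` term is the per-year interaction
    OR (e.g. 0.96/year for a declining trend).
    """
    base = design or DesignSpec()
    design = DesignSpec(covariates=base.covariates, extras=base.extras,
                        age_interaction=True, age_center=base.age_center)
    return fit_binary_logistic(df, gene, "case", design)


def trend_constraint(K: int, p: int, exposure_index: int) -> np.ndarray:
    """Constraint matrix for the ordered-trend model.

    Non-exposure coefficients are free per category; the exposure log-OR in
    category k (1-based level code) is gamma * k with a single shared gamma
    placed as the last reduced parameter.
    """
    free = [(k, j) for k in range(K) for j in range(p) if j != exposure_index]
    A = np.zeros((K * p, len(free) + 1))
    for col, (k, j) in enumerate(free):
        A[k * p + j, col] = 1.0
    for k in range(K):
        A[k * p + exposure_index, len(free)] = float(k + 1)
    return A


def fit_ordered_trend(df: pd.DataFrame, gene: str, outcome_col: str,
                      levels: list, design: DesignSpec | None = None):
    """Multinomial model with the exposure log-OR linear in the outcome level.

    ``levels`` lists the ordered case categories (level codes 1..K).  Returns
    ``(gamma, se, fit)`` where gamma is the per-level log-OR slope; the
    saturated model for a likelihood-ratio test can be fitted with
    :func:`fit_multinomial_cc` on the same categories.
    """
    design = design or DesignSpec()
    sub = _gene_subset(df, gene)
    keep = (sub["status"] == "control") | sub[outcome_col].isin(levels)
    sub = sub[keep]
    carrier = (sub["gene"] == gene).to_numpy()
    y = np.zeros(len(sub), int)
    for k, lev in enumerate(levels):
        y[(sub[outcome_col] == lev).to_numpy()] = k + 1
    X, names = build_design(sub, carrier, design)
    K, p = len(levels), X.shape[1]
    A = trend_constraint(K, p, names.index("carrier"))
    fit = fit_multinomial(X, y, K=K, constraint=A, term_names=names,
                          categories=list(levels))
    gamma = fit.get(levels[0], "carrier")   # coef at level 1 == gamma * 1
    se = fit.se(levels[0], "carrier")
    return gamma, se, fit


def subtype_heterogeneity_lrt(cases: pd.DataFrame, gene: str,
                               design: DesignSpec | None = None,
                               subtype_col: str = "intrinsic_subtype",
                               categories: list | None = None) -> dict:
    """Case-only likelihood-ratio test for etiologic heterogeneity by subtype.

    Fits a multinomial model of subtype (first category as reference) on
    carrier status plus covariates among cases, against the model without
    the carrier term.  Returns ``{"statistic", "df", "p"}`` with
    df = K - 1.
    """
    design = design or DesignSpec()
    categories = list(categories or SUBTYPES)
    sub = _gene_subset(cases, gene)
    sub = sub[(sub["status"] == "case") & sub[subtype_col].isin(categories)]
    carrier = (sub["gene"] == gene).to_numpy()
    if carrier.sum() == 0:
        raise ValueError(f"no {gene} carriers among cases")
    present = [c for c in categories if (sub[subtype_col] == c).any()]
    y = np.zeros(len(sub), int)
    for k, cat in enumerate(present[1:]):
        y[(sub[subtype_col] == cat).to_numpy()] = k + 1
    K = len(present) - 1
    X_full, names = build_design(sub, carrier, design)
    full = fit_multinomial(X_full, y, K=K, term_names=names,
                           categories=present[1:])
    drop = [j for j, nm in enumerate(names) if nm != "carrier"]
    X_null = X_full[:, drop]
    null = fit_multinomial(X_null, y, K=K,
                           term_names=[names[j] for j in drop],
                           categories=present[1:])
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return {"statistic": stat, "df": K, "p": float(stats.chi2.sf(stat, K))}


def rubin_pool(points, variances) -> PooledEstimate:
    """Combine per-imputation estimates with Rubin's rules.

    T = W + (1 + 1/m) B; the reference distribution is t with the
    Barnard-Rubin (infinite complete-data) degrees of freedom.
    """
    points = np.asarray(points, float)
    variances = np.asarray(variances, float)
    m = len(points)
    if m < 1:
        raise ValueError("need at least one estimate")
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    point = float(points.mean())
    W = float(variances.mean())
    B = float(points.var(ddof=1)) if m > 1 else 0.0
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        r = (1.0 + 1.0 / m) * B / W
        df = (m - 1) * (1.0 + 1.0 / r) ** 2
    else:
        df = np.inf
    tq = stats.t.ppf(0.975, df) if np.isfinite(df) else 1.959963984540054
    se = np.sqrt(T)
    ci = (point - tq * se, point + tq * se)
    if np.isfinite(df):
        p = float(2 * stats.t.sf(abs(point) / se, df))
    else:
        p = float(2 * stats.norm.sf(abs(point) / se))
    return PooledEstimate(point=point, within_var=W, between_var=B,
                          total_var=T, m=m, df=float(df), ci=ci, p=p)
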