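"""End-to-end analysis steps that stitch the modules together.

These are the operations the pipeline and the analysis scripts run: impute
markers, construct subtypes per imputed data set, fit the case-control
multinomial model, and pool with Rubin's rules — or, alternatively, weight
the regression by the EM posterior subtype probabilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import (DesignSpec, ORFit,
                          fit_multinomial_cc, rubin_pool)
from .imputation import em_fit, em_subtype_weight_matrix, mice_impute
from .subtyping import MISSING, SUBTYPES, classify_dataframe

MARKERS = ["er", "pr", "erbb2", "grade"]


def complete_case_subtype_ors(cohort: pd.DataFrame, gene: str,
                              design: DesignSpec | None = None,
                              subtype_col: str = "intrinsic_subtype") -> ORFit:
    """Case-control subtype ORs using only cases with a determined subtype."""
    if subtype_col not in cohort.columns:
        cohort = classify_dataframe(cohort)
    return fit_multinomial_cc(cohort, gene, design=design,
                              subtype_col=subtype_col)


def mice_pooled_subtype_ors(cohort: pd.DataFrame, gene: str, m: int = 100,
                            cycles: int = 10, seed: int = 0,
                            design: DesignSpec | None = None):
    """MICE -> subtype construction -> multinomial fit -> Rubin pooling.

    Returns ``(table, pooled)`` where ``table`` is the tidy OR table (one
    row per subtype: OR, ci_low, ci_high, p, n_carriers, model_tag) and
    ``pooled`` maps subtype -> :class:`PooledEstimate` of the log-OR.
    """
    cases = cohort[cohort["status"] == "case"].reset_index(drop=True)
    controls = cohort[cohort["status"] == "control"]
    imp = mice_impute(cases, m=m, cycles=cycles, seed=seed)
    per_cat: dict = {s: ([], []) for s in SUBTYPES}
    for ds in imp.datasets:
        completed = pd.concat([ds, controls], ignore_index=True)
        completed = classify_dataframe(completed)
        fit = fit_multinomial_cc(completed, gene, design=design)
        for s in fit.categories:
            per_cat[s][0].append(fit.get(s, "carrier"))
            per_cat[s][1].append(fit.se(s, "carrier") ** 2)
    pooled = {}
    rows = []
    n_carriers = int(((cohort["gene"] == gene)
                      & (cohort["status"] == "case")).sum())
    for s in SUBTYPES:
        points, variances = per_cat[s]
        if len(points) < imp.m:
            continue  # category dropped in at least one imputed data set
        est = rubin_pool(points, variances)
        pooled[s] = est
        rows.append({
            "gene": gene, "outcome_category": s, "OR": np.exp(est.point),
            "ci_low": np.exp(est.ci[0]), "ci_high": np.exp(est.ci[1]),
            "p": est.p, "n_carriers": n_carriers, "model_tag": "mice_pooled",
        })
    return pd.DataFrame(rows), pooled


def em_weighted_subtype_ors(cohort: pd.DataFrame, gene: str,
                            design: DesignSpec | None = None,
                            tol: float = 1e-8) -> ORFit:
    """Subtype ORs with cases fractionally weighted by EM posteriors.

    The joint marker-cell distribution is fitted on all cases (unstratified
    by genotype); each case then contributes to every subtype category with
    its posterior probability, and the weighted case-control multinomial
    model is maximized as usual.
    """
    cases = cohort[cohort["status"] == "case"].reset_index(drop=True)
    controls = cohort[cohort["status"] == "control"].copy()
    model = em_fit(cases, tol=tol)
    W = em_subtype_weight_matrix(model, cases)
    parts, weights = [], []
    controls["intrinsic_subtype"] = MISSING
    parts.append(controls)
    weights.append(np.ones(len(controls)))
    for j, s in enumerate(SUBTYPES):
        sel = W[:, j] > 1e-12
        if not sel.any():
            continue
        chunk = cases[sel].copy()
        chunk["intrinsic_subtype"] = s
        parts.append(chunk)
        weights.append(W[sel, j])
    expanded = pd.concat(parts, ignore_index=True)
    w = np.concatenate(weights)
    return fit_multinomial_cc(expanded, gene, design=design, weights=w)
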