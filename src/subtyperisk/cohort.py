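"""Synthetic case-control cohort generator.

Simulates subject-level records with the structure the downstream analyses
assume: controls carry a rare variant at the population frequency; cases are
enriched for carriers according to the configured subtype odds ratios, with
the latent true subtype drawn conditional on the carried gene and age, and
the immunohistochemistry markers drawn conditional on the true subtype (the
inverse of the classification rules, so that classification on fully
observed markers recovers the latent subtype exactly).

Under the rare-disease model with subtype-specific odds ratios
``OR_{g,s}(a) = OR_{g,s} * theta_g**(a - ref_age)`` the odds of carrying
gene *g* among cases of age *a* are the population odds multiplied by
``C_g(a) = sum_s pi_s * OR_{g,s}(a)``, and the subtype of a carrier case is
drawn with probability proportional to ``pi_s * OR_{g,s}(a)``.  This makes
the empirical per-subtype case-control odds ratio converge to the configured
``OR_{g,s}(a)`` — the property every parameter-recovery test relies on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .config import GeneratorConfig, MSV_GENES
from .subtyping import MISSING, SUBTYPES

MARKER_COLS = ["er", "pr", "erbb2", "grade"]

COHORT_COLUMNS = [
    "subject_id", "status", "age", "country", "gene", "carrier_class",
    "er", "pr", "erbb2", "grade", "size_cat", "node", "stage", "true_subtype",
]

# fixed marginals for the prognostic fields of cases (not subtype-linked)
SIZE_CATS = ["<2cm", "2-5cm", ">5cm"]
SIZE_PROBS = [0.55, 0.38, 0.07]
NODE_CATS = ["neg", "pos"]
NODE_PROBS = [0.65, 0.35]
STAGE_CATS = ["I", "II", "III"]
STAGE_PROBS = [0.45, 0.40, 0.15]


def _truncated_ages(n, mean, sd, bounds, rng):
    lo, hi = bounds
    a, b = (lo - 0.5 - mean) / sd, (hi + 0.5 - mean) / sd
    ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(ages), lo, hi).astype(int)


def _draw_categorical(p_matrix, rng):
    """Row-wise categorical draw; p_matrix is (n, k) with rows summing to 1."""
    c = np.cumsum(p_matrix, axis=1)
    u = rng.random((p_matrix.shape[0], 1))
    return (u > c).sum(axis=1)


def apply_missingness(df, rates, rng, mode="MCAR"):
    """Independently blank marker fields of case rows at the given rates.

    ``rates`` maps marker column name -> probability in [0, 1].  In ``MAR``
    mode the per-subject rate additionally depends on age and country
    (higher for older subjects and for the first country alphabetically),
    which stresses imputation beyond the missing-completely-at-random
    setting; missingness never depends on carrier state in either mode.
    """
    for m, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missingness rate for {m!r} must be in [0, 1], got {r}")
    out = df.copy()
    is_case = out["status"].to_numpy() == "case"
    n = len(out)
    for m, r in rates.items():
        if r == 0:
            continue
        if mode == "MCAR" or r == 1:
            p = np.full(n, r)
        else:  # MAR: logistic shift in age and country
            age = out["age"].to_numpy(float)
            first_country = out["country"] == sorted(out["country"].unique())[0]
            base = logit(np.clip(r, 1e-9, 1 - 1e-9))
            p = expit(base + 0.03 * (age - 50.0) + 0.5 * first_country.to_numpy())
        hit = (rng.random(n) < p) & is_case
        col = out[m].to_numpy(object).copy()
        col[hit] = MISSING
        out[m] = col
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a cohort as a DataFrame with :data:`COHORT_COLUMNS`.

    Deterministic: the same config (including seed) yields byte-identical
    CSV output.  Controls have empty tumor fields; ``true_subtype`` is the
    latent simulation truth, retained for testing only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    pi = np.array([config.baseline_subtype_props[s] for s in SUBTYPES])
    countries = sorted(config.countries)
    cw = np.array([config.countries[c] for c in countries], float)
    cw = cw / cw.sum()

    # ---- controls: population carrier frequencies --------------------
    nco = config.n_controls
    ctrl_age = _truncated_ages(nco, config.control_age_mean,
                               config.control_age_sd, config.age_bounds, rng)
    ctrl_country = rng.choice(len(countries), size=nco, p=cw)
    p_genes = np.array([config.carrier_freq[g] for g in genes])
    probs = np.concatenate([[1.0 - p_genes.sum()], p_genes])
    ctrl_gene_idx = _draw_categorical(np.tile(probs, (nco, 1)), rng)

    # ---- cases: carrier enrichment, latent subtype, markers -----------
    nca = config.n_cases
    case_age = _truncated_ages(nca, config.case_age_mean,
                               config.case_age_sd, config.age_bounds, rng)
    case_country = rng.choice(len(countries), size=nca, p=cw)

    # carrier odds among cases multiplied by C_g(age)
    weights = np.empty((nca, len(genes) + 1))
    weights[:, 0] = 1.0 - p_genes.sum()
    or_mat = np.array([[config.subtype_or[g][s] for s in SUBTYPES] for g in genes])
    for j, g in enumerate(genes):
        theta = config.age_trend.get(g, 1.0)
        trend = theta ** (case_age - config.ref_age)
        weights[:, j + 1] = p_genes[j] * trend * (pi @ or_mat[j])
    weights /= weights.sum(axis=1, keepdims=True)
    case_gene_idx = _draw_categorical(weights, rng)

    # subtype | gene: proportional to pi_s * OR_{g,s} (the shared per-gene
    # age factor cancels within the normalisation)
    subtype_probs = np.tile(pi, (nca, 1))
    for j in range(len(genes)):
        sel = case_gene_idx == j + 1
        subtype_probs[sel] = pi * or_mat[j]
    subtype_probs /= subtype_probs.sum(axis=1, keepdims=True)
    subtype_idx = _draw_categorical(subtype_probs, rng)

    # markers | subtype
    er = np.empty(nca, object)
    pr = np.empty(nca, object)
    erbb2 = np.empty(nca, object)
    grade = np.empty(nca, object)
    for si, s in enumerate(SUBTYPES):
        sel = np.flatnonzero(subtype_idx == si)
        if sel.size == 0:
            continue
        cells = list(config.marker_given_subtype[s])
        cp = np.array([config.marker_given_subtype[s][c] for c in cells])
        cp = cp / cp.sum()
        pick = rng.choice(len(cells), size=sel.size, p=cp)
        arr = np.array(cells, dtype=object)
        er[sel], pr[sel], erbb2[sel], grade[sel] = (
            arr[pick, 0], arr[pick, 1], arr[pick, 2], arr[pick, 3])

    size_cat = np.array(SIZE_CATS, object)[rng.choice(3, size=nca, p=SIZE_PROBS)]
    node = np.array(NODE_CATS, object)[rng.choice(2, size=nca, p=NODE_PROBS)]
    stage = np.array(STAGE_CATS, object)[rng.choice(3, size=nca, p=STAGE_PROBS)]
    for arr in (size_cat, node, stage):
        arr[rng.random(nca) < config.other_field_missingness] = MISSING

    # carrier class: PTV, with an MSV share for the genes that have them
    def carrier_classes(gene_idx, n):
        cls = np.where(gene_idx > 0, "PTV", MISSING).astype(object)
        u = rng.random(n)
        for j, g in enumerate(genes):
            if g in MSV_GENES:
                sel = (gene_idx == j + 1) & (u < config.msv_fraction)
                cls[sel] = "MSV"
        return cls

    case_class = carrier_classes(case_gene_idx, nca)
    ctrl_class = carrier_classes(ctrl_gene_idx, nco)

    gene_labels = np.array([MISSING] + genes, dtype=object)
    cases = pd.DataFrame({
        "subject_id": [f"case_{i + 1:06d}" for i in range(nca)],
        "status": "case",
        "age": case_age,
        "country": np.array(countries, object)[case_country],
        "gene": gene_labels[case_gene_idx],
        "carrier_class": case_class,
        "er": er, "pr": pr, "erbb2": erbb2, "grade": grade,
        "size_cat": size_cat, "node": node, "stage": stage,
        "true_subtype": np.array(SUBTYPES, object)[subtype_idx],
    })
    controls = pd.DataFrame({
        "subject_id": [f"ctrl_{i + 1:06d}" for i in range(nco)],
        "status": "control",
        "age": ctrl_age,
        "country": np.array(countries, object)[ctrl_country],
        "gene": gene_labels[ctrl_gene_idx],
        "carrier_class": ctrl_class,
        "er": MISSING, "pr": MISSING, "erbb2": MISSING, "grade": MISSING,
        "size_cat": MISSING, "node": MISSING, "stage": MISSING,
        "true_subtype": MISSING,
    })

    cohort = pd.concat([cases, controls], ignore_index=True)[COHORT_COLUMNS]
    cohort = apply_missingness(cohort, config.missingness, rng,
                               mode=config.missingness_mode)
    return cohort


def empirical_subtype_or(cohort: pd.DataFrame, gene: str, subtype: str,
                         subtype_col: str = "true_subtype") -> float:
    """Crude 2x2 case-control OR for carriers of ``gene`` vs a subtype.

    Cases restricted to the given subtype; carriers of other genes excluded
    from both arms.  Serves as the model-free oracle for parameter-recovery
    tests on the latent complete data.
    """
    keep = cohort["gene"].isin([MISSING, gene])
    df = cohort[keep]
    carrier = df["gene"] == gene
    is_case = (df["status"] == "case") & (df[subtype_col] == subtype)
    is_ctrl = df["status"] == "control"
    a = int((carrier & is_case).sum())
    b = int((~carrier & is_case).sum())
    c = int((carrier & is_ctrl).sum())
    d = int((~carrier & is_ctrl).sum())
    if min(a, b, c, d) == 0:
        raise ZeroDivisionError("empty cell in 2x2 table")
    return (a * d) / (b * c)
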