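"""Intrinsic-like breast tumor subtypes from immunohistochemistry and grade.

Five surrogate ("intrinsic-like") subtypes are defined from estrogen receptor
(ER), progesterone receptor (PR) and ERBB2 (HER2) status plus histological
grade.  Hormone receptor (HR) status is positive if ER or PR is positive and
negative only if both are negative.  Grades 1-2 count as low/intermediate
grade, grade 3 as high grade; grade is only needed to split the HR+/ERBB2-
group.

The classifier is a total function: any marker required by the applicable
rule that is missing yields ``UNDETERMINED``.
"""

from __future__ import annotations

from itertools import product

# marker value encodings used throughout the package
NEG = "neg"
POS = "pos"
MISSING = ""  # empty string == missing, matching the CSV convention

HRPOS_ERBB2NEG_LOW = "HRpos_ERBB2neg_low"
HRPOS_ERBB2NEG_HIGH = "HRpos_ERBB2neg_high"
HRPOS_ERBB2POS = "HRpos_ERBB2pos"
HRNEG_ERBB2POS = "HRneg_ERBB2pos"
TN = "TN"
UNDETERMINED = "undetermined"

SUBTYPES = [
    HRPOS_ERBB2NEG_LOW,
    HRPOS_ERBB2NEG_HIGH,
    HRPOS_ERBB2POS,
    HRNEG_ERBB2POS,
    TN,
]

GRADES = ("1", "2", "3")

#: the 24 fully crossed (er, pr, erbb2, grade) cells
CELLS = [
    (er, pr, erbb2, grade)
    for er, pr, erbb2, grade in product((NEG, POS), (NEG, POS), (NEG, POS), GRADES)
]


def _hr_status(er: str, pr: str) -> str:
    """HR positive iff ER or PR positive; negative iff both observed negative.

    If one receptor is missing and the other is negative, HR status cannot be
    resolved (the missing one could be positive) and '' is returned.
    """
    if er == POS or pr == POS:
        return POS
    if er == NEG and pr == NEG:
        return NEG
    return MISSING


def classify(er: str, pr: str, erbb2: str, grade: str) -> str:
    """Map marker values to one of the five intrinsic-like subtypes.

    Parameters are ``"neg"``/``"pos"`` (grade: ``"1"``/``"2"``/``"3"``), with
    ``""`` for missing.  Returns a subtype label or ``"undetermined"`` when a
    marker the applicable rule needs is missing.
    """
    hr = _hr_status(er, pr)
    if hr == MISSING:
        return UNDETERMINED
    if hr == POS:
        if erbb2 == POS:
            return HRPOS_ERBB2POS
        if erbb2 == NEG:
            if grade in ("1", "2"):
                return HRPOS_ERBB2NEG_LOW
            if grade == "3":
                return HRPOS_ERBB2NEG_HIGH
            return UNDETERMINED  # grade needed to split HR+/ERBB2-
        return UNDETERMINED  # ERBB2 missing
    # HR negative (ER- and PR-)
    if erbb2 == POS:
        return HRNEG_ERBB2POS
    if erbb2 == NEG:
        return TN  # grade not required
    return UNDETERMINED


def compatible_cells(er: str, pr: str, erbb2: str, grade: str) -> list[tuple]:
    """Fully observed cells consistent with the (possibly partial) markers."""
    ers = (NEG, POS) if er == MISSING else (er,)
    prs = (NEG, POS) if pr == MISSING else (pr,)
    erbb2s = (NEG, POS) if erbb2 == MISSING else (erbb2,)
    grades = GRADES if grade == MISSING else (grade,)
    return [c for c in product(ers, prs, erbb2s, grades)]


def cells_for_subtype(subtype: str) -> list[tuple]:
    """All fully observed marker cells that classify to ``subtype``."""
    return [c for c in CELLS if classify(*c) == subtype]


def classify_dataframe(df, er="er", pr="pr", erbb2="erbb2", grade="grade"):
    """Add/replace an ``intrinsic_subtype`` column on a cohort DataFrame.

    Controls (rows with all four marker fields missing and status 'control')
    get an empty subtype.
    """
    out = df.copy()
    # vectorized via the 108 possible observed patterns
    markers = out[[er, pr, erbb2, grade]].fillna(MISSING).astype(str)
    key = markers[er] + "|" + markers[pr] + "|" + markers[erbb2] + "|" + markers[grade]
    lut = {
        k: classify(*k.split("|", 3))
        for k in key.unique()
    }
    out["intrinsic_subtype"] = key.map(lut)
    out.loc[out["status"] == "control", "intrinsic_subtype"] = MISSING
    return out
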