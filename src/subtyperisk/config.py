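"""Configuration for the synthetic case-control cohort generator.

The generator emulates a large European case-control breast-cancer study:
~40-50k cases and controls aged 18-79 from a handful of countries, rare
(<0.1%-1%) germline carriers of protein-truncating (PTV) or pathogenic rare
missense (MSV) variants in nine susceptibility genes, subtype-specific odds
ratios that may decline log-linearly with age, and heavy missingness in the
pathology markers (ER 18%, grade 18%, PR 32%, ERBB2 43%).

Default per-gene odds ratios use the study's published point estimates where
those are printed; the remaining cells are filled with values consistent with
the published qualitative pattern (see docs/methods.md) and are marked
arbitrary there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import subtyping
from .subtyping import SUBTYPES


class ConfigError(ValueError):
    """Raised when a GeneratorConfig field violates its constraints."""


GENES = [
    "ATM",
    "BARD1",
    "BRCA1",
    "BRCA2",
    "CHEK2",
    "PALB2",
    "RAD51C",
    "RAD51D",
    "TP53",
]

#: genes for which rare pathogenic missense carriers are generated
MSV_GENES = ("BRCA1", "BRCA2", "TP53")

# Published point estimates where available; remaining cells chosen to match
# the qualitative pattern (documented as arbitrary in the methods note).
DEFAULT_SUBTYPE_OR = {
    "BRCA1": {"HRpos_ERBB2neg_low": 3.26, "HRpos_ERBB2neg_high": 13.5,
              "HRpos_ERBB2pos": 2.27, "HRneg_ERBB2pos": 9.85, "TN": 55.32},
    "BRCA2": {"HRpos_ERBB2neg_low": 5.0, "HRpos_ERBB2neg_high": 11.53,
              "HRpos_ERBB2pos": 4.0, "HRneg_ERBB2pos": 6.0, "TN": 10.07},
    "ATM": {"HRpos_ERBB2neg_low": 2.0, "HRpos_ERBB2neg_high": 4.99,
            "HRpos_ERBB2pos": 1.8, "HRneg_ERBB2pos": 1.8, "TN": 1.0},
    "CHEK2": {"HRpos_ERBB2neg_low": 2.5, "HRpos_ERBB2neg_high": 2.5,
              "HRpos_ERBB2pos": 2.5, "HRneg_ERBB2pos": 2.5, "TN": 1.0},
    "PALB2": {"HRpos_ERBB2neg_low": 3.0, "HRpos_ERBB2neg_high": 9.43,
              "HRpos_ERBB2pos": 3.0, "HRneg_ERBB2pos": 3.0, "TN": 8.05},
    "BARD1": {"HRpos_ERBB2neg_low": 1.5, "HRpos_ERBB2neg_high": 3.0,
              "HRpos_ERBB2pos": 1.5, "HRneg_ERBB2pos": 2.0, "TN": 10.05},
    "RAD51C": {"HRpos_ERBB2neg_low": 1.2, "HRpos_ERBB2neg_high": 1.5,
               "HRpos_ERBB2pos": 1.2, "HRneg_ERBB2pos": 1.5, "TN": 6.19},
    "RAD51D": {"HRpos_ERBB2neg_low": 1.2, "HRpos_ERBB2neg_high": 2.5,
               "HRpos_ERBB2pos": 1.5, "HRneg_ERBB2pos": 1.5, "TN": 6.19},
    "TP53": {"HRpos_ERBB2neg_low": 1.5, "HRpos_ERBB2neg_high": 2.0,
             "HRpos_ERBB2pos": 5.0, "HRneg_ERBB2pos": 7.0, "TN": 1.0},
}

#: per-year multiplicative OR trend around the reference age
DEFAULT_AGE_TREND = {
    "ATM": 1.0, "BARD1": 1.0, "BRCA1": 0.96, "BRCA2": 0.96, "CHEK2": 0.99,
    "PALB2": 1.0, "RAD51C": 1.0, "RAD51D": 1.0, "TP53": 1.0,
}

#: realistic rare-carrier population frequencies (all < 1%)
DEFAULT_CARRIER_FREQ = {
    "ATM": 0.004, "BARD1": 0.001, "BRCA1": 0.002, "BRCA2": 0.003,
    "CHEK2": 0.005, "PALB2": 0.002, "RAD51C": 0.001, "RAD51D": 0.001,
    "TP53": 0.0005,
}

#: subtype distribution among noncarrier cases
DEFAULT_BASELINE_PROPS = {
    "HRpos_ERBB2neg_low": 0.55, "HRpos_ERBB2neg_high": 0.15,
    "HRpos_ERBB2pos": 0.10, "HRneg_ERBB2pos": 0.05, "TN": 0.15,
}

DEFAULT_MISSINGNESS = {"er": 0.18, "grade": 0.18, "pr": 0.32, "erbb2": 0.43}

DEFAULT_COUNTRIES = {
    "UK": 0.30, "Germany": 0.25, "Sweden": 0.20,
    "Netherlands": 0.15, "Australia": 0.10,
}


def _uniform_marker_given_subtype() -> dict:
    """Uniform distribution over the marker cells compatible with each subtype."""
    out = {}
    for s in SUBTYPES:
        cells = subtyping.cells_for_subtype(s)
        out[s] = {c: 1.0 / len(cells) for c in cells}
    return out


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Ages are integer years, truncated to the study's inclusion window
    [18, 79].  ``subtype_or`` holds, per gene, the odds ratio at ``ref_age``
    for each intrinsic-like subtype versus controls; ``age_trend`` is the
    multiplicative per-year factor applied to every subtype OR of that gene.
    """

    genes: list = field(default_factory=lambda: list(GENES))
    carrier_freq: dict = field(default_factory=lambda: dict(DEFAULT_CARRIER_FREQ))
    subtype_or: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_SUBTYPE_OR.items()})
    age_trend: dict = field(default_factory=lambda: dict(DEFAULT_AGE_TREND))
    ref_age: float = 50.0
    baseline_subtype_props: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_PROPS))
    n_cases: int = 10000
    n_controls: int = 10000
    countries: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRIES))
    case_age_mean: float = 55.8
    case_age_sd: float = 10.6
    control_age_mean: float = 55.1
    control_age_sd: float = 11.9
    age_bounds: tuple = (18, 79)
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    missingness_mode: str = "MCAR"  # or "MAR": rate shifts with age/country
    marker_given_subtype: dict = field(default_factory=_uniform_marker_given_subtype)
    msv_fraction: float = 0.2
    other_field_missingness: float = 0.10
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> "GeneratorConfig":
        if not self.genes:
            raise ConfigError("genes: must list at least one gene")
        for g in self.genes:
            if g not in self.carrier_freq:
                raise ConfigError(f"carrier_freq: missing entry for gene {g!r}")
            if not 0.0 <= self.carrier_freq[g] <= 1.0:
                raise ConfigError(f"carrier_freq[{g}]: {self.carrier_freq[g]} not in [0, 1]")
            if g not in self.subtype_or:
                raise ConfigError(f"subtype_or: missing entry for gene {g!r}")
            for s in SUBTYPES:
                if s not in self.subtype_or[g]:
                    raise ConfigError(f"subtype_or[{g}]: missing subtype {s!r}")
                if self.subtype_or[g][s] <= 0:
                    raise ConfigError(f"subtype_or[{g}][{s}]: must be > 0")
            if self.age_trend.get(g, 1.0) <= 0:
                raise ConfigError(f"age_trend[{g}]: must be > 0")
        if sum(self.carrier_freq[g] for g in self.genes) >= 1.0:
            raise ConfigError("carrier_freq: per-gene frequencies must sum to < 1")
        tot = sum(self.baseline_subtype_props.get(s, 0.0) for s in SUBTYPES)
        if abs(tot - 1.0) > 1e-12:
            raise ConfigError(f"baseline_subtype_props: sums to {tot}, expected 1")
        for s in SUBTYPES:
            dist = self.marker_given_subtype.get(s)
            if dist is None:
                raise ConfigError(f"marker_given_subtype: missing subtype {s!r}")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"marker_given_subtype[{s}]: does not sum to 1")
            for cell, p in dist.items():
                if p < 0:
                    raise ConfigError(f"marker_given_subtype[{s}][{cell}]: negative")
                if p > 0 and subtyping.classify(*cell) != s:
                    raise ConfigError(
                        f"marker_given_subtype[{s}]: cell {cell} would not classify to {s}"
                    )
        for m, r in self.missingness.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"missingness[{m}]: {r} not in [0, 1]")
        if self.missingness_mode not in ("MCAR", "MAR"):
            raise ConfigError("missingness_mode: must be 'MCAR' or 'MAR'")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("n_cases/n_controls: must be nonnegative")
        if not self.countries:
            raise ConfigError("countries: must be nonempty")
        lo, hi = self.age_bounds
        if not (18 <= lo < hi <= 79):
            raise ConfigError("age_bounds: must lie within the inclusion window [18, 79]")
        if not 0.0 <= self.msv_fraction <= 1.0:
            raise ConfigError("msv_fraction: not in [0, 1]")
        return self

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Copy with fields replaced (convenience for tests and scripts)."""
        return replace(self, **kwargs)


def single_gene_config(gene: str, carrier_freq: float = 0.01,
                       subtype_or: dict | None = None,
                       age_trend: float | None = None,
                       **kwargs) -> GeneratorConfig:
    """A config with one gene only — the parameter-recovery workhorse.

    Defaults to the gene's default OR vector and age trend; ``age_trend``
    may be overridden (e.g. 1.0 to switch the trend off).
    """
    ors = dict(subtype_or or DEFAULT_SUBTYPE_OR[gene])
    trend = DEFAULT_AGE_TREND[gene] if age_trend is None else age_trend
    return GeneratorConfig(
        genes=[gene],
        carrier_freq={gene: carrier_freq},
        subtype_or={gene: ors},
        age_trend={gene: trend},
        **kwargs,
    )
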