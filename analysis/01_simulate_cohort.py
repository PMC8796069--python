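#!/usr/bin/env python
"""Generate the working synthetic cohort.

Draws a desk-scale case-control cohort (15,000 cases + 15,000 controls,
nine susceptibility genes at their default rare frequencies and subtype
odds ratios, marker missingness at the study rates) and writes it to
results/cohort.csv.
"""

from pathlib import Path

from subtyperisk.cohort import generate_cohort
from subtyperisk.config import GeneratorConfig
from subtyperisk.io import write_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240101


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = GeneratorConfig(n_cases=15000, n_controls=15000, seed=SEED)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, OUT / "cohort.csv")

    cases = cohort[cohort["status"] == "case"]
    print(f"cohort: {len(cohort)} subjects "
          f"({len(cases)} cases, {len(cohort) - len(cases)} controls)")
    print(f"mean age cases {cases['age'].mean():.1f}, "
          f"controls {cohort[cohort.status == 'control']['age'].mean():.1f}")
    carriers = cases[cases["gene"] != ""]
    print(f"carrier cases: {len(carriers)} "
          f"({100 * len(carriers) / len(cases):.2f}% of cases)")
    print(carriers["gene"].value_counts().to_string())
    miss = {m: f"{(cases[m] == '').mean():.1%}"
            for m in ("er", "pr", "erbb2", "grade")}
    print(f"marker missingness among cases: {miss}")
    print(f"wrote {OUT / 'cohort.csv'}")


if __name__ == "__main__":
    main()
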