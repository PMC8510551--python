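"""Screen-level classification: robust 3-SD outlier calls and enrichment.

Joins the fitness, growth and morphology tables produced by steps 02-04,
flags strains beyond 3 robust SD of the relevant reference (nontargeting
controls for fitness; all strains for lag and dimensions), counts hits per
category, and tests functional-group enrichment among the flagged sets
with the exact hypergeometric tail. Writes results/classification_*.
"""

import argparse
from pathlib import Path

from phenoscreen.io import read_table, write_table
from phenoscreen.stats import classify_screen

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(k: float = 3.0) -> None:
    fitness = read_table(RESULTS / "fitness.csv")
    growth = read_table(RESULTS / "growth_features.csv")
    growth = growth[(growth["strain_id"] != "WT")
                    & growth["lag_norm"].notna()]
    morph = (read_table(RESULTS / "morphology.csv")
             .groupby("strain_id", as_index=False)
             [["corrected_length", "corrected_width"]].median())

    annotations = fitness[["strain_id", "category"]].copy()
    # growth/morphology rows use their own strain ids; annotate as essential
    extra = set(growth["strain_id"]) | set(morph["strain_id"])
    extra -= set(annotations["strain_id"])
    if extra:
        import pandas as pd

        annotations = pd.concat([
            annotations,
            pd.DataFrame({"strain_id": sorted(extra),
                          "category": "essential"}),
        ], ignore_index=True)

    result = classify_screen(annotations, fitness=fitness, growth=growth,
                             morphology=morph, k=k)
    import pandas as pd

    write_table(pd.DataFrame([result.counts]),
                RESULTS / "classification_counts.csv")
    (RESULTS / "classification_summary.txt").write_text(result.summary_text())
    print(result.summary_text())


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--k", type=float, default=3.0)
    main(**vars(ap.parse_args()))
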