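"""Simulate the pooled CRISPRi competition and the arrayed purity assay.

Generates the synthetic inputs every later step consumes: a spacer library
(essential / nonessential / nontargeting-control strains), spacer counts
before and after 15 control doublings at finite sequencing depth, a
ground-truth fitness table, and per-well counts with one well carrying a
planted 1% cross-contamination. Tables land in results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from phenoscreen.fitness import SampleCounts
from phenoscreen.io import write_counts, write_table
from phenoscreen.simulate import (
    ScreenSimConfig,
    simulate_contamination,
    simulate_pooled_screen,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = ScreenSimConfig(n_essential=282, n_nonessential=187, n_controls=48,
                          doublings=15.0, read_depth=2_000_000, seed=seed)
    library, t0, t_end, truth = simulate_pooled_screen(cfg)
    write_table(library.table, RESULTS / "library.csv")
    write_counts(t0, RESULTS / "counts_t0.csv")
    write_counts(t_end, RESULTS / "counts_induced.csv")
    write_table(truth, RESULTS / "fitness_truth.csv")

    # arrayed purity assay: 8 wells, one with 1% bleed from its neighbour
    spacers = library.spacers[:8]
    wells = {f"well{i}": SampleCounts(f"well{i}", "t0", {spacers[i]: 5e5})
             for i in range(8)}
    mix = pd.DataFrame(np.eye(8), index=wells.keys(), columns=wells.keys())
    mix.iloc[0, 0], mix.iloc[0, 1] = 0.99, 0.01
    mixed, contam_truth = simulate_contamination(wells, mix,
                                                 read_depth=500_000,
                                                 seed=seed + 1)
    for well_id, counts in mixed.items():
        write_counts(counts, RESULTS / f"well_{well_id}.csv")
    write_table(contam_truth, RESULTS / "contamination_truth.csv")

    print(f"pooled screen: {cfg.n_strains} strains "
          f"({cfg.n_essential} essential, {cfg.n_nonessential} nonessential, "
          f"{cfg.n_controls} controls) at depth {cfg.read_depth:,}")
    print(f"purity assay: {len(mixed)} wells, planted 1% bleed into well0")
    print(f"tables written under {RESULTS}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
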