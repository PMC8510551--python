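"""End-to-end pipeline orchestration from a single YAML config.

A run executes, in dependency order, any enabled subset of: pooled-screen
simulation + relative fitness, plate simulation + growth features,
cell-population simulation + morphometrics, and the screen-level robust
classification over whatever upstream tables exist. Every output is a CSV
with a parameter-echo header; a rerun with the same config and seed
reproduces every table byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitness import relative_fitness
from .growth import analyze_plate, curves_from_long
from .io import write_table
from .morphology import cell_dimensions, filter_and_summarize, plate_correct
from .simulate import (
    CellSimConfig,
    GrowthSimConfig,
    ScreenSimConfig,
    simulate_cell_population,
    simulate_growth_plate,
    simulate_pooled_screen,
)
from .stats import classify_screen

log = logging.getLogger("phenoscreen")


@dataclass
class RunConfig:
    outdir: str = "phenoscreen_run"
    seed: int = 0
    run_fitness: bool = True
    run_growth: bool = True
    run_morphology: bool = True
    run_classify: bool = True
    # pooled screen
    n_essential: int = 100
    n_nonessential: int = 60
    n_controls: int = 48
    doublings: float = 15.0
    read_depth: int = 1_000_000
    pseudocount: float = 0.5
    # growth
    n_wells: int = 96
    n_wt_wells: int = 24
    window: int = 5
    sample_interval: float = 8.5
    duration: float = 600.0
    growth_noise_sd: float = 0.002
    # morphology
    n_cells_per_strain: int = 120
    n_morph_strains: int = 12
    min_width: float = 0.6
    max_width: float = 2.0
    min_cells: int = 100
    # classification
    k_sd: float = 3.0
    contamination_cutoff: float = 1e-4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _header(cfg: RunConfig, stage: str) -> str:
    return (f"phenoscreen v{__version__} stage={stage} seed={cfg.seed} "
            f"D={cfg.doublings} window={cfg.window} "
            f"width_bounds=[{cfg.min_width},{cfg.max_width}] "
            f"min_cells={cfg.min_cells} k={cfg.k_sd}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns a manifest of outputs and counts."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "outputs": {}}
    fitness_df = growth_df = morph_df = None
    annotations = None

    if cfg.run_fitness:
        scfg = ScreenSimConfig(
            n_essential=cfg.n_essential, n_nonessential=cfg.n_nonessential,
            n_controls=cfg.n_controls, doublings=cfg.doublings,
            read_depth=cfg.read_depth, seed=cfg.seed,
        )
        library, t0, t_end, truth = simulate_pooled_screen(scfg)
        fitness_df = relative_fitness(t0, t_end, library,
                                      doublings=cfg.doublings,
                                      pseudocount=cfg.pseudocount)
        path = out / "fitness.csv"
        write_table(fitness_df, path, _header(cfg, "fitness"))
        write_table(truth, out / "fitness_truth.csv", _header(cfg, "fitness"))
        manifest["outputs"]["fitness"] = str(path)
        manifest["n_strains"] = len(fitness_df)
        annotations = truth[["strain_id", "category"]].copy()
        log.info("fitness: %d strains", len(fitness_df))

    if cfg.run_growth:
        gcfg = GrowthSimConfig(
            sample_interval=cfg.sample_interval, duration=cfg.duration,
            noise_sd=cfg.growth_noise_sd, seed=cfg.seed + 1,
        )
        curves_long, truth = simulate_growth_plate(
            gcfg, cfg.n_wells, mu_range=(0.01, 0.04), lag_range=(0.0, 120.0))
        wt_long, wt_truth = simulate_growth_plate(
            GrowthSimConfig(sample_interval=cfg.sample_interval,
                            duration=cfg.duration,
                            noise_sd=cfg.growth_noise_sd, seed=cfg.seed + 2),
            cfg.n_wt_wells, mu_range=(0.028, 0.032), lag_range=(40.0, 80.0))
        wt_long["well"] = "wt_" + wt_long["well"]
        strain_ids = ([f"s{i:04d}" for i in range(cfg.n_wells)]
                      if fitness_df is None
                      else fitness_df["strain_id"].iloc[:cfg.n_wells].tolist())
        plate_map = pd.concat([
            pd.DataFrame({"well": truth["well"],
                          "strain": strain_ids[:len(truth)], "plate": "g1"}),
            pd.DataFrame({"well": "wt_" + wt_truth["well"],
                          "strain": "WT", "plate": "g1"}),
        ])
        curves = curves_from_long(pd.concat([curves_long, wt_long]), plate_map)
        growth_df = analyze_plate(curves, wt_strain="WT", window=cfg.window)
        growth_df = growth_df.rename(columns={"strain_id": "strain_id"})
        path = out / "growth.csv"
        write_table(growth_df, path, _header(cfg, "growth"))
        write_table(truth, out / "growth_truth.csv", _header(cfg, "growth"))
        manifest["outputs"]["growth"] = str(path)
        log.info("growth: %d wells", len(growth_df))

    if cfg.run_morphology:
        n_strains = cfg.n_morph_strains
        rng = np.random.default_rng(cfg.seed + 3)
        dims_rows = []
        strain_ids = ([f"s{i:04d}" for i in range(n_strains)]
                      if fitness_df is None
                      else fitness_df["strain_id"].iloc[:n_strains].tolist())
        plate_offsets = {"m1": (0.0, 0.0), "m2": (0.15, 0.05)}
        for si, sid in enumerate(strain_ids):
            # plates partition strains: each strain is imaged on one plate
            plate = "m1" if si % 2 == 0 else "m2"
            ccfg = CellSimConfig(
                n_cells=cfg.n_cells_per_strain,
                length_mean=float(rng.uniform(2.5, 4.0)),
                width_mean=float(rng.uniform(0.9, 1.1)),
                plate_offsets={plate: plate_offsets[plate]},
                seed=cfg.seed + 100 + si,
            )
            cells, _ = simulate_cell_population(ccfg)
            for plate_id, contour in cells:
                d = cell_dimensions(contour)
                dims_rows.append((sid, plate_id, d.cell_id, d.length, d.width,
                                  d.area, d.volume, d.method))
        dims = pd.DataFrame(dims_rows, columns=[
            "strain_id", "plate_id", "cell_id", "length_um", "width_um",
            "area_um2", "volume_um3", "method"])
        write_table(dims, out / "cell_dims.csv", _header(cfg, "morphology"))
        summaries = filter_and_summarize(
            dims, min_width=cfg.min_width, max_width=cfg.max_width,
            min_cells=cfg.min_cells)
        kept = summaries[summaries["included"]]
        if kept.empty:
            log.warning("morphology: no strain met the %d-cell rule",
                        cfg.min_cells)
            morph_df = kept
        else:
            morph_df = plate_correct(kept)
        path = out / "morphology.csv"
        write_table(morph_df, path, _header(cfg, "morphology"))
        manifest["outputs"]["morphology"] = str(path)
        log.info("morphology: %d strains summarised", len(morph_df))

    if cfg.run_classify and annotations is not None:
        morph_in = None
        if morph_df is not None:
            morph_in = (morph_df.groupby("strain_id", as_index=False)
                        [["corrected_length", "corrected_width"]].median())
        growth_in = None
        if growth_df is not None:
            growth_in = growth_df[(growth_df["strain_id"] != "WT")
                                  & growth_df["lag_norm"].notna()]
        result = classify_screen(
            annotations, fitness=fitness_df, growth=growth_in,
            morphology=morph_in, k=cfg.k_sd)
        path = out / "classification_counts.csv"
        write_table(pd.DataFrame([result.counts]), path, _header(cfg, "classify"))
        (out / "classification_summary.txt").write_text(result.summary_text())
        manifest["outputs"]["classification"] = str(path)
        manifest["counts"] = result.counts

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
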