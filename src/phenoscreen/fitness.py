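"""Pooled relative fitness from sgRNA spacer counts, and contamination QC.

A pooled competition starts from a mixed library at t0 and grows for D
doublings (of the nontargeting control strains); deep sequencing of the
20-nt sgRNA spacers before and after measures each strain's share of the
pool. The relative fitness of strain i,

    RF_i = 1 + (L_i - median_ctrl L) / D,   L_i = log2(f_end,i / f_t0,i),

is its number of doublings relative to the controls: RF = 1 means the
strain kept pace, RF = 0 means it did not divide, negative RF means it was
depleted faster than dilution alone explains. Frequencies f are read-depth
normalised within each sample; the control median anchors RF = 1.

The same counting machinery drives arrayed-well purity QC: the most
abundant unexpected spacer in a well defines the contamination fraction,
and wells above 1e-4 are called cross-contaminated.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SpacerLibrary",
    "SampleCounts",
    "ContaminationReport",
    "load_library",
    "count_spacers",
    "relative_fitness",
    "contamination_report",
]

SPACER_LEN = 20
_DNA = set("ACGT")


@dataclass(frozen=True)
class SpacerLibrary:
    """The designed spacer set: strain_id, 20-nt spacer, gene, category."""

    table: pd.DataFrame  # columns: strain_id, spacer, gene, category [, plate, well]

    def __post_init__(self):
        t = self.table
        required = {"strain_id", "spacer", "gene", "category"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"library missing columns: {sorted(missing)}")
        if t["spacer"].duplicated().any():
            dups = t.loc[t["spacer"].duplicated(), "spacer"].tolist()
            raise ValueError(f"duplicate spacers in library: {dups[:5]}")
        bad = [s for s in t["spacer"]
               if len(s) != SPACER_LEN or not set(s) <= _DNA]
        if bad:
            raise ValueError(f"spacers must be {SPACER_LEN}-nt ACGT: {bad[:5]}")
        bad_cat = set(t["category"]) - {"essential", "nonessential", "control"}
        if bad_cat:
            raise ValueError(f"unknown categories: {sorted(bad_cat)}")

    @property
    def spacers(self) -> list[str]:
        return self.table["spacer"].tolist()

    @property
    def control_strains(self) -> list[str]:
        t = self.table
        return t.loc[t["category"] == "control", "strain_id"].tolist()

    def strain_of(self, spacer: str) -> str:
        row = self.table.loc[self.table["spacer"] == spacer, "strain_id"]
        if row.empty:
            raise KeyError(spacer)
        return str(row.iloc[0])


@dataclass
class SampleCounts:
    """Per-sample spacer counts. Counts may be real-valued (expected counts
    from a noise-free simulation) or integer (observed reads)."""

    sample_id: str
    condition: str  # t0 | uninduced | induced
    counts: dict[str, float]
    replicate: int = 1
    unmapped: float = 0.0
    ambiguous: float = 0.0

    @property
    def total_mapped(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def total_reads(self) -> float:
        return self.total_mapped + self.unmapped + self.ambiguous

    def scaled(self, factor: float) -> "SampleCounts":
        return SampleCounts(
            self.sample_id, self.condition,
            {s: c * factor for s, c in self.counts.items()},
            self.replicate, self.unmapped * factor, self.ambiguous * factor,
        )


@dataclass(frozen=True)
class ContaminationReport:
    well_id: str
    expected_spacer: str
    major_contaminant_spacer: str | None
    contaminant_fraction: float
    contaminated: bool
    cutoff: float = 1e-4


def load_library(path: str | Path) -> SpacerLibrary:
    return SpacerLibrary(pd.read_csv(path, dtype=str))


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_spacers(
    reads,
    library: SpacerLibrary,
    sample_id: str = "sample",
    condition: str = "t0",
    replicate: int = 1,
) -> SampleCounts:
    """Count exact spacer occurrences in reads.

    ``reads`` is a FASTQ path (optionally .gz) or an iterable of sequence
    strings / Bio.SeqRecords. A read increments exactly one spacer when
    exactly one library spacer occurs verbatim as a substring; reads
    matching no spacer are tallied as unmapped and reads matching two or
    more as ambiguous. No mismatches are tolerated: the spacer doubles as
    an error-free barcode.
    """
    spacer_set = {}
    for sp in library.spacers:
        spacer_set[sp] = 0.0
    kmer_to_spacer = {sp: sp for sp in spacer_set}  # spacers are the k-mers

    unmapped = 0
    ambiguous = 0

    def _iter_seqs():
        if isinstance(reads, (str, Path)):
            with _open_maybe_gz(reads) as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    yield str(rec.seq)
        else:
            for r in reads:
                yield str(getattr(r, "seq", r))

    for seq in _iter_seqs():
        seq = seq.upper()
        hits = set()
        for i in range(len(seq) - SPACER_LEN + 1):
            kmer = seq[i:i + SPACER_LEN]
            sp = kmer_to_spacer.get(kmer)
            if sp is not None:
                hits.add(sp)
                if len(hits) > 1:
                    break
        if len(hits) == 1:
            spacer_set[hits.pop()] += 1
        elif not hits:
            unmapped += 1
        else:
            ambiguous += 1

    return SampleCounts(sample_id, condition, spacer_set, replicate,
                        unmapped=unmapped, ambiguous=ambiguous)


def relative_fitness(
    t0: SampleCounts,
    t_end: SampleCounts,
    library: SpacerLibrary,
    doublings: float = 15.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Relative fitness per strain from start/end spacer counts.

    Frequencies use ``(count + pseudocount) / sum(count + pseudocount)``;
    the pseudocount (default 0.5) keeps strains that drop to zero reads at
    t_end representable, and 0 is allowed when counts are guaranteed
    positive. RF is not clamped: a strain diluted out faster than the pool
    grows has RF < 0.

    Returns a DataFrame with strain_id, gene, category, condition,
    replicate, log2fc and rf; the median control RF is exactly 1.
    """
    if doublings <= 0:
        raise ValueError("doublings must be positive")
    lib = library.table
    controls = set(library.control_strains)
    if not controls:
        raise ValueError("no control strains in library")

    spacers = lib["spacer"].tolist()
    missing = [s for s in spacers if s not in t0.counts or s not in t_end.counts]
    if missing:
        raise ValueError(f"samples do not cover library: {missing[:3]}")

    c0 = np.array([t0.counts[s] for s in spacers], dtype=float) + pseudocount
    c1 = np.array([t_end.counts[s] for s in spacers], dtype=float) + pseudocount
    if np.any(c0 <= 0) or np.any(c1 <= 0):
        raise ValueError(
            "zero counts with pseudocount 0: log2 fold change undefined"
        )
    f0 = c0 / c0.sum()
    f1 = c1 / c1.sum()
    log2fc = np.log2(f1 / f0)

    is_ctrl = lib["strain_id"].isin(controls).to_numpy()
    ctrl_median = float(np.median(log2fc[is_ctrl]))
    rf = 1.0 + (log2fc - ctrl_median) / doublings

    return pd.DataFrame({
        "strain_id": lib["strain_id"].values,
        "gene": lib["gene"].values,
        "category": lib["category"].values,
        "condition": t_end.condition,
        "replicate": t_end.replicate,
        "log2fc": log2fc,
        "rf": rf,
    })


def combine_replicates(fitness_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average RF (and log2fc) across replicate fitness tables by mean."""
    cat = pd.concat(fitness_tables, ignore_index=True)
    keys = ["strain_id", "gene", "category", "condition"]
    out = cat.groupby(keys, as_index=False, sort=False).agg(
        n_replicates=("replicate", "nunique"),
        log2fc=("log2fc", "mean"),
        rf=("rf", "mean"),
    )
    return out


def contamination_report(
    well_counts: SampleCounts,
    expected_spacer: str,
    library: SpacerLibrary,
    cutoff: float = 1e-4,
) -> ContaminationReport:
    """Purity QC for one arrayed well.

    The contamination fraction is the share of *mapped* reads belonging to
    the most abundant spacer other than the expected one; a well is called
    contaminated when the fraction strictly exceeds the cutoff.
    """
    if expected_spacer not in set(library.spacers):
        raise ValueError("expected spacer not in library")
    total = well_counts.total_mapped
    if total <= 0:
        raise ValueError(f"well {well_counts.sample_id}: no mapped reads")
    others = {s: c for s, c in well_counts.counts.items()
              if s != expected_spacer and c > 0}
    if not others:
        return ContaminationReport(well_counts.sample_id, expected_spacer,
                                   None, 0.0, False, cutoff)
    major = max(others, key=others.get)
    frac = others[major] / total
    return ContaminationReport(
        well_counts.sample_id, expected_spacer, major,
        float(frac), bool(frac > cutoff), cutoff,
    )


def contamination_table(reports: list[ContaminationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.well_id, r.expected_spacer, r.major_contaminant_spacer or "",
          r.contaminant_fraction, r.contaminated) for r in reports],
        columns=["well_id", "expected_spacer", "major_contaminant_spacer",
                 "contaminant_fraction", "contaminated"],
    )
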