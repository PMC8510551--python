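"""Plain-text I/O for the tabular interchange formats.

Contours travel as long-format CSV (cell_id, frame, vertex_index, x_um,
y_um); counts, libraries, plate maps and all result tables are CSV. Floats
are written with a fixed format so a rerun with the same seed produces
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitness import SampleCounts
from .morphology import CellContour

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_contours(cells: list[tuple[str, CellContour]] | list[CellContour],
                   path: str | Path) -> None:
    rows = []
    for item in cells:
        plate, contour = item if isinstance(item, tuple) else ("", item)
        for vi, (x, y) in enumerate(contour.vertices):
            rows.append((contour.cell_id, plate, contour.frame, vi, x, y))
    df = pd.DataFrame(rows, columns=["cell_id", "plate_id", "frame",
                                     "vertex_index", "x_um", "y_um"])
    write_table(df, path)


def read_contours(path: str | Path) -> list[tuple[str, CellContour]]:
    df = read_table(path)
    out = []
    for (cid, frame), grp in df.groupby(["cell_id", "frame"], sort=False):
        grp = grp.sort_values("vertex_index")
        plate = str(grp["plate_id"].iloc[0]) if "plate_id" in grp else ""
        verts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        out.append((plate, CellContour(cell_id=str(cid), vertices=verts,
                                       frame=int(frame))))
    return out


def write_counts(counts: SampleCounts, path: str | Path) -> None:
    df = pd.DataFrame({
        "spacer": list(counts.counts.keys()),
        "count": list(counts.counts.values()),
    })
    write_table(df, path, header_comment=(
        f"sample_id={counts.sample_id} condition={counts.condition} "
        f"replicate={counts.replicate} unmapped={counts.unmapped:g} "
        f"ambiguous={counts.ambiguous:g}"
    ))


def read_counts(path: str | Path, sample_id: str = "",
                condition: str = "t0") -> SampleCounts:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    df = read_table(path)
    return SampleCounts(
        sample_id or meta.get("sample_id", Path(path).stem),
        meta.get("condition", condition),
        dict(zip(df["spacer"], df["count"].astype(float))),
        replicate=int(meta.get("replicate", 1)),
        unmapped=float(meta.get("unmapped", 0)),
        ambiguous=float(meta.get("ambiguous", 0)),
    )
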