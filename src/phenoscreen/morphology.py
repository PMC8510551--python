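"""Single-cell morphometrics from segmented contours.

Rod-shaped bacteria are measured in a cell-intrinsic coordinate system
built by meshing the contour: the two poles (the boundary points farthest
apart) split the outline into two arcs, transverse ribs connect the arcs,
and the midline through the rib midpoints is relaxed until every rib is
perpendicular to it. Cell length is the pole-to-pole arc length of the
midline; width is the mean rib width after excluding ribs inside the polar
caps and at septation sites (deep local constrictions of a dividing cell);
volume treats the cell as a solid of revolution of the rib-radius profile
about the midline. Cells that have lost rod shape make the mesh fail
(``RodShapeError``), and their dimensions fall back to the extents along
the principal axes of the contour.

Per-strain summaries use robust statistics: cells with implausible widths
(< 0.6 or > 2.0 um, segmentation debris and clumps) are eliminated first,
strains keep their medians only when at least 100 cells survive, spread is
the MAD-based coefficient of variation, and systematic plate-to-plate
imaging offsets are removed by median-centering each plate onto the global
median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from skimage import measure, segmentation

from .growth import smooth_ma
from .stats import MAD_TO_SD

__all__ = [
    "CellContour",
    "MidlineMesh",
    "CellDims",
    "TimeLapseTrack",
    "RodShapeError",
    "mesh_contour",
    "cell_dimensions",
    "cell_volume",
    "principal_axis_dims",
    "instantaneous_growth",
    "cell_fluorescence",
    "filter_and_summarize",
    "plate_correct",
    "segment_mask",
    "spherocylinder_volume",
]

WIDTH_MIN_UM = 0.6
WIDTH_MAX_UM = 2.0
MIN_CELLS = 100
SEPTUM_FRACTION = 0.75  # rib width below this fraction of the median => septal
ROD_ASPECT_MARGIN = 1.05  # midline must exceed max rib width by this factor


class RodShapeError(ValueError):
    """Meshing failed: the contour is not rod-like (fall back to principal axes)."""


@dataclass
class CellContour:
    cell_id: str
    vertices: np.ndarray  # (n, 2) closed simple polygon, um
    frame: int = 0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")
        # drop an explicit closing vertex
        if v.shape[0] > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 16:
            raise ValueError("contour needs >= 16 vertices")
        self.vertices = v

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class MidlineMesh:
    midline: np.ndarray        # (m, 2) pole-to-pole polyline, um
    ribs_a: np.ndarray         # (m, 2) rib endpoints on one arc
    ribs_b: np.ndarray         # (m, 2) rib endpoints on the other arc
    rib_widths: np.ndarray     # (m,) um; zero at the two poles
    pole_indices: np.ndarray | None = None    # ribs inside the polar caps
    septum_indices: np.ndarray | None = None  # ribs at septation sites

    @property
    def midline_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.midline, axis=0), axis=1)))

    @property
    def arc_positions(self) -> np.ndarray:
        """Arc-length position of each rib along the midline (from pole 1)."""
        seg = np.linalg.norm(np.diff(self.midline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class CellDims:
    cell_id: str
    length: float   # um
    width: float    # um
    area: float     # um^2
    volume: float   # um^3
    method: str     # "mesh" | "principal_axes"
    frame: int = 0


@dataclass
class TimeLapseTrack:
    cell_id: str
    dims: list[CellDims]       # time-ordered, one per frame
    interval: float            # min between frames
    rate_series: np.ndarray | None = None  # (1/V) dV/dt per frame, min^-1


# ---------------------------------------------------------------------------
# geometry helpers

def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline at n points equally spaced in arc length."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return np.repeat(pts[:1], n, axis=0)
    target = np.linspace(0.0, cum[-1], n)
    x = np.interp(target, cum, pts[:, 0])
    y = np.interp(target, cum, pts[:, 1])
    return np.column_stack([x, y])


def _line_polyline_intersections(p: np.ndarray, d: np.ndarray,
                                 poly: np.ndarray) -> np.ndarray:
    """All intersections of the infinite line through p with direction d
    with an open polyline; returns (k, 2) points (possibly empty)."""
    s0 = poly[:-1]
    s1 = poly[1:]
    # signed cross products of segment ends about the line
    c0 = d[0] * (s0[:, 1] - p[1]) - d[1] * (s0[:, 0] - p[0])
    c1 = d[0] * (s1[:, 1] - p[1]) - d[1] * (s1[:, 0] - p[0])
    hit = (c0 * c1 <= 0) & (c0 != c1)
    if not hit.any():
        return np.empty((0, 2))
    u = c0[hit] / (c0[hit] - c1[hit])
    return s0[hit] + u[:, None] * (s1[hit] - s0[hit])


def _nearest_intersection(p: np.ndarray, d: np.ndarray,
                          poly: np.ndarray) -> np.ndarray | None:
    pts = _line_polyline_intersections(p, d, poly)
    if pts.shape[0] == 0:
        return None
    return pts[np.argmin(np.linalg.norm(pts - p, axis=1))]


def _find_poles(boundary: np.ndarray) -> tuple[int, int]:
    """Indices of the two boundary points of maximal separation."""
    n = boundary.shape[0]
    if n > 720:  # coarse pass then refine, keeps O(n^2) bounded
        step = n // 720 + 1
        coarse = boundary[::step]
        d = np.linalg.norm(coarse[:, None] - coarse[None], axis=2)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        return i * step, j * step
    d = np.linalg.norm(boundary[:, None] - boundary[None], axis=2)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return int(i), int(j)


# ---------------------------------------------------------------------------
# meshing

def mesh_contour(
    contour: CellContour,
    n_ribs: int | None = None,
    max_iter: int = 40,
    angle_tol_deg: float = 5.0,
) -> MidlineMesh:
    """Build the midline/rib mesh of a rod-shaped cell contour.

    The poles are the pair of boundary points with maximal separation; the
    boundary splits into two pole-to-pole arcs. Starting from
    arc-length-matched point pairs, the midline (rib midpoints) is relaxed
    iteratively: at each pass ribs are re-cast along the normals of the
    current midline and must end within ``angle_tol_deg`` of perpendicular
    to it. Non-convergence, a self-intersecting midline, or a midline not
    clearly longer than the widest rib (aspect margin 1.05) raise
    ``RodShapeError``, signalling a cell that has lost rod shape.
    """
    poly = contour.polygon
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("contour is not a valid simple polygon")

    boundary = _resample_polyline(
        np.vstack([contour.vertices, contour.vertices[:1]]),
        max(256, contour.vertices.shape[0]),
    )[:-1]
    n = boundary.shape[0]
    i, j = _find_poles(boundary)
    if i > j:
        i, j = j, i
    arc1 = boundary[i:j + 1]
    arc2 = np.vstack([boundary[j:], boundary[:i + 1]])[::-1]  # pole1 -> pole2
    pole1, pole2 = boundary[i], boundary[j]

    m = n_ribs if n_ribs is not None else max(25, n // 8) | 1
    A = _resample_polyline(arc1, m)
    B = _resample_polyline(arc2, m)
    mid = 0.5 * (A + B)
    scale = float(np.linalg.norm(pole2 - pole1))
    if scale <= 0:
        raise RodShapeError("degenerate contour: coincident poles")

    converged = False
    damping = 0.5  # under-relaxation; the cap stations are stiff
    n_smooth = max(1, m // 16)  # zigzag suppression scales with rib count
    prev_mid = None
    for _ in range(max_iter):
        mid = _resample_polyline(mid, m)
        mid[0], mid[-1] = pole1, pole2
        # light smoothing suppresses the zigzag mode of the relaxation
        for _pass in range(n_smooth):
            sm = mid.copy()
            sm[1:-1] = (mid[:-2] + 2 * mid[1:-1] + mid[2:]) / 4.0
            mid = sm
        tang = np.gradient(mid, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        newA, newB = A.copy(), B.copy()
        for s in range(1, m - 1):
            qa = _nearest_intersection(mid[s], normal[s], arc1)
            qb = _nearest_intersection(mid[s], normal[s], arc2)
            if qa is not None:
                newA[s] = qa
            if qb is not None:
                newB[s] = qb
        newA[0] = newB[0] = pole1
        newA[-1] = newB[-1] = pole2
        target = 0.5 * (newA + newB)
        new_mid = mid + damping * (target - mid)
        shift = float(np.max(np.linalg.norm(new_mid - prev_mid, axis=1))) \
            if prev_mid is not None else np.inf
        prev_mid = new_mid
        A, B, mid = newA, newB, new_mid
        if shift < 2e-4 * scale:
            converged = True
            break
    if not converged:
        raise RodShapeError("midline relaxation did not converge")

    # perpendicularity check on interior ribs
    tang = np.gradient(mid, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    rib_vec = B - A
    widths = np.linalg.norm(rib_vec, axis=1)
    interior = widths > 1e-9
    interior[0] = interior[-1] = False
    if interior.any():
        cosang = np.abs(np.sum(rib_vec[interior] * tang[interior], axis=1)
                        / widths[interior])
        max_dev = float(np.degrees(np.arcsin(np.clip(cosang, 0, 1))).max())
        if max_dev > angle_tol_deg:
            raise RodShapeError(
                f"ribs deviate {max_dev:.1f} deg from perpendicular"
            )

    midline = LineString(mid)
    if not midline.is_simple:
        raise RodShapeError("midline self-intersects")
    mesh = MidlineMesh(midline=mid, ribs_a=A, ribs_b=B, rib_widths=widths)
    if mesh.midline_length <= ROD_ASPECT_MARGIN * widths.max():
        raise RodShapeError("midline not longer than max rib width: not a rod")
    return mesh


def _flag_poles_and_septa(mesh: MidlineMesh,
                          septum_fraction: float = SEPTUM_FRACTION) -> None:
    """Mark ribs inside the polar caps and at septation sites on the mesh.

    Cap extent is half the interior median width (measured along the
    midline from each pole), refined once after the first exclusion pass.
    Septal ribs are contiguous runs of local width minima dipping below
    ``septum_fraction`` of the cell's median rib width.
    """
    pos = mesh.arc_positions
    L = mesh.midline_length
    w = mesh.rib_widths
    nonzero = w > 1e-9

    w0 = float(np.median(w[nonzero]))
    for _ in range(2):  # one refinement pass
        cap = w0 / 2.0
        in_pole = (pos < cap) | (pos > L - cap) | ~nonzero
        if (~in_pole).sum() >= 3:
            w0 = float(np.median(w[~in_pole]))
    cap = w0 / 2.0
    pole_idx = np.where((pos < cap) | (pos > L - cap) | ~nonzero)[0]

    body = np.setdiff1d(np.arange(w.size), pole_idx)
    septum_idx = np.array([], dtype=int)
    if body.size >= 5:
        med = float(np.median(w[body]))
        below = np.zeros(w.size, dtype=bool)
        below[body] = w[body] < septum_fraction * med
        # keep only runs of below-threshold ribs containing a local minimum
        idx = np.where(below)[0]
        runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1) if idx.size else []
        keep = [r for r in runs if r.size > 0]
        if keep:
            septum_idx = np.concatenate(keep)
    mesh.pole_indices = pole_idx
    mesh.septum_indices = septum_idx


def cell_volume(mesh: MidlineMesh) -> float:
    """Volume of the solid of revolution of the rib profile about the midline.

    Conical frustums between adjacent ribs (rib radius = half width, zero
    at the poles) integrate pi * r(s)^2 along the midline; the tapering rib
    profile inside the caps reproduces the hemispherical cap volume in the
    fine-mesh limit.
    """
    if mesh.rib_widths.size < 3:
        raise ValueError("need >= 3 ribs for a volume")
    r = mesh.rib_widths / 2.0
    s = mesh.arc_positions
    h = np.diff(s)
    r0, r1 = r[:-1], r[1:]
    return float(np.sum(np.pi / 3.0 * h * (r0 ** 2 + r0 * r1 + r1 ** 2)))


def spherocylinder_volume(length: float, width: float) -> float:
    """Closed-form volume of a spherocylinder (cylinder + hemispherical caps).

    ``length`` is pole-to-pole; degenerates to a sphere at length == width.
    """
    r = width / 2.0
    cyl = max(length - width, 0.0)
    return np.pi * r ** 2 * cyl + 4.0 / 3.0 * np.pi * r ** 3


def principal_axis_dims(contour: CellContour) -> CellDims:
    """Fallback dimensions: extents along the contour's principal axes."""
    boundary = _resample_polyline(
        np.vstack([contour.vertices, contour.vertices[:1]]), 512)[:-1]
    centered = boundary - boundary.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T
    length = float(np.ptp(proj[:, 0]))
    width = float(np.ptp(proj[:, 1]))
    if width > length:
        length, width = width, length
    return CellDims(
        cell_id=contour.cell_id, frame=contour.frame,
        length=length, width=width,
        area=float(contour.polygon.area),
        volume=spherocylinder_volume(length, width),
        method="principal_axes",
    )


def cell_dimensions(
    contour: CellContour,
    septum_fraction: float = SEPTUM_FRACTION,
    force_principal_axes: bool = False,
) -> CellDims:
    """Length, width, area and volume of one cell.

    Mesh path: length is the pole-to-pole midline arc length; width the
    mean rib width excluding polar-cap and septal ribs. When the mesh
    fails (``RodShapeError``) — or ``force_principal_axes`` is set, as for
    datasets of grossly deformed cells — dimensions are the principal-axis
    extents of the contour instead.
    """
    if force_principal_axes:
        return principal_axis_dims(contour)
    try:
        mesh = mesh_contour(contour)
    except RodShapeError:
        return principal_axis_dims(contour)
    _flag_poles_and_septa(mesh, septum_fraction)
    excluded = set(mesh.pole_indices.tolist()) | set(mesh.septum_indices.tolist())
    keep = np.array([i for i in range(mesh.rib_widths.size) if i not in excluded])
    if keep.size == 0:
        return principal_axis_dims(contour)
    width = float(mesh.rib_widths[keep].mean())
    return CellDims(
        cell_id=contour.cell_id, frame=contour.frame,
        length=mesh.midline_length, width=width,
        area=float(contour.polygon.area),
        volume=cell_volume(mesh),
        method="mesh",
    )


# ---------------------------------------------------------------------------
# time lapse

def instantaneous_growth(track: TimeLapseTrack, window: int = 3) -> np.ndarray:
    """Per-frame relative volumetric growth rate (1/V) dV/dt in min^-1.

    V(t) is lightly smoothed (moving average, 3 frames) before central
    differencing; endpoints use one-sided differences. Exponential growth
    at rate g gives a flat series at g; linear volume growth gives a
    strictly decreasing series.
    """
    if len(track.dims) < 3:
        raise ValueError("need >= 3 frames")
    V = np.array([d.volume for d in track.dims], dtype=float)
    if np.any(V <= 0):
        raise ValueError("nonpositive volume in track")
    t = np.arange(V.size) * track.interval
    Vs = smooth_ma(V, window)
    rate = np.gradient(Vs, t) / Vs
    track.rate_series = rate
    return rate


# ---------------------------------------------------------------------------
# fluorescence

def cell_fluorescence(
    image: np.ndarray,
    contour: CellContour,
    background: float,
    pixel_size: float = 1.0,
) -> float:
    """Background-subtracted intensity per unit projected cell area.

    Sums (pixel - background) over pixels whose centers fall inside the
    contour polygon and divides by the polygon area. Image rows map to y
    and columns to x, both scaled by ``pixel_size`` (um/px).
    """
    img = np.asarray(image, dtype=float)
    rows, cols = np.indices(img.shape)
    cx = (cols.ravel() + 0.5) * pixel_size
    cy = (rows.ravel() + 0.5) * pixel_size
    inside = shapely.contains_xy(contour.polygon, cx, cy)
    if not inside.any():
        raise ValueError("contour encloses no pixel centers")
    total = float(np.sum(img.ravel()[inside] - background))
    return total / float(contour.polygon.area)


# ---------------------------------------------------------------------------
# strain-level aggregation

def filter_and_summarize(
    dims: pd.DataFrame,
    min_width: float = WIDTH_MIN_UM,
    max_width: float = WIDTH_MAX_UM,
    min_cells: int = MIN_CELLS,
    width_filter: bool = True,
) -> pd.DataFrame:
    """Robust per-strain morphology summaries.

    ``dims`` needs columns strain_id, length_um, width_um and optionally
    plate_id/condition. Cells with width strictly below ``min_width`` or
    strictly above ``max_width`` are eliminated; strains with fewer than
    ``min_cells`` surviving cells keep their row but are flagged
    ``included = False``. CV is the MAD-based robust SD over the median.
    ``width_filter=False`` disables the width gate for datasets of
    deliberately deformed cells.
    """
    df = dims.copy()
    if "plate_id" not in df.columns:
        df["plate_id"] = "plate1"
    if width_filter:
        df = df[(df["width_um"] >= min_width) & (df["width_um"] <= max_width)]
    rows = []
    for (strain, plate), grp in df.groupby(["strain_id", "plate_id"], sort=False):
        n = len(grp)
        med_l = float(grp["length_um"].median())
        med_w = float(grp["width_um"].median())
        mad_l = float((grp["length_um"] - med_l).abs().median())
        mad_w = float((grp["width_um"] - med_w).abs().median())
        rows.append((
            strain, plate, n, med_l, med_w,
            MAD_TO_SD * mad_l / med_l if med_l > 0 else np.nan,
            MAD_TO_SD * mad_w / med_w if med_w > 0 else np.nan,
            n >= min_cells,
        ))
    return pd.DataFrame(rows, columns=[
        "strain_id", "plate_id", "n_cells", "median_length", "median_width",
        "cv_length", "cv_width", "included",
    ])


def plate_correct(
    summaries: pd.DataFrame,
    columns: tuple[str, str] = ("median_length", "median_width"),
) -> pd.DataFrame:
    """Remove per-plate offsets by median-centering onto the global median.

    For each dimension, corrected = value - median(plate) + median(global),
    so every plate's median lands exactly on the global median and a single
    plate passes through unchanged.
    """
    if summaries.empty:
        raise ValueError("empty summary table")
    out = summaries.copy()
    for col in columns:
        global_med = float(out[col].median())
        plate_med = out.groupby("plate_id")[col].transform("median")
        out["corrected_" + col.removeprefix("median_")] = (
            out[col] - plate_med + global_med
        )
    return out


# ---------------------------------------------------------------------------
# synthetic-mask segmentation

def segment_mask(mask: np.ndarray, pixel_size: float) -> list[CellContour]:
    """Extract cell contours from a binary mask.

    Connected components touching the image border are discarded; each
    remaining component's boundary is traced with marching squares at the
    0.5 level (subpixel) and converted to um (x = col * pixel_size,
    y = row * pixel_size, y-down raster convention, contours stored
    counterclockwise in that frame).
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return []
    labels = measure.label(m)
    labels = segmentation.clear_border(labels)
    contours = []
    for region in measure.regionprops(labels):
        sl = region.slice
        pad = np.pad(labels[sl] == region.label, 1).astype(float)
        traced = measure.find_contours(pad, 0.5)
        if not traced:
            continue
        tr = max(traced, key=len)
        # back to full-image pixel coordinates, then to um
        rows = tr[:, 0] - 1 + sl[0].start
        cols = tr[:, 1] - 1 + sl[1].start
        verts = np.column_stack([cols, rows]) * pixel_size
        if verts.shape[0] < 17:
            continue
        poly = Polygon(verts)
        if not poly.exterior.is_ccw:
            verts = verts[::-1]
        contours.append(CellContour(cell_id=f"cell_{region.label}",
                                    vertices=verts))
    return contours
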