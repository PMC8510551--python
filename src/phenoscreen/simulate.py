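"""Synthetic-data generators with known ground truth.

Every stage of the screen pipeline has a forward model here, so parameter
recovery can be tested end to end without any raw data:

* pooled screen — strain abundances evolve as a_i * 2^(d_i) over the
  competition (d_i = doublings of strain i while controls complete D);
  reads are drawn multinomially at a chosen depth, or left as expected
  counts in the noise-free ("infinite depth") mode;
* plate-reader growth — OD follows od0 * exp(integral of mu(t)) with a
  logistic ramp in mu(t) whose half-max crossing sits exactly at the lag
  target, a logistic cap at carrying capacity, and additive Gaussian OD
  noise at the instrument's 8.5-min cadence;
* cell populations — spherocylinder contours (rectangle of length L - W
  capped by semicircles of diameter W) with per-plate additive offsets on
  length and width, randomly rotated and translated, optionally rasterised
  to binary masks;
* single-cell time lapse — a cell elongating at constant width so that
  volume grows exponentially (or linearly, for the degenerate-growth
  variant);
* well cross-contamination — per-well read mixtures under a known mixing
  matrix.

Each generator returns a truth table; fixing the seed fixes every
generated artifact bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .fitness import SampleCounts, SpacerLibrary
from .morphology import (
    CellContour,
    TimeLapseTrack,
    cell_dimensions,
)

__all__ = [
    "ScreenSimConfig",
    "GrowthSimConfig",
    "CellSimConfig",
    "simulate_pooled_screen",
    "simulate_growth_curve",
    "simulate_growth_plate",
    "simulate_cell_population",
    "simulate_time_lapse",
    "simulate_contamination",
    "spherocylinder_contour",
    "rasterize_contour",
    "reads_for_counts",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))
# constant scaffold around the spacer in simulated amplicon reads
SCAFFOLD_5P = "GTTTTAGAGCTAGAAATAGCAAG"[:12]
SCAFFOLD_3P = "TTTAAGAGCTATGCTGGAAACAGC"[:12]


@dataclass
class ScreenSimConfig:
    """Forward model of the pooled competition experiment."""

    n_essential: int = 282
    n_nonessential: int = 187
    n_controls: int = 48          # pool carried ~50 nontargeting controls
    doublings: float = 15.0       # control doublings D over the competition
    read_depth: int | None = 1_000_000  # None => expected counts, no sampling
    true_fitness: np.ndarray | None = None  # per-strain d_i (doublings)
    t0_abundance: np.ndarray | None = None  # relative abundance at t0
    overdispersion: float = 0.0   # Dirichlet-multinomial concentration scale
    seed: int = 0

    @property
    def n_strains(self) -> int:
        return self.n_essential + self.n_nonessential + self.n_controls

    def __post_init__(self):
        if self.n_controls < 1:
            raise ValueError("need >= 1 control strain")
        if self.read_depth is not None and self.read_depth <= 0:
            raise ValueError("read_depth must be positive (or None)")
        if self.doublings <= 0:
            raise ValueError("doublings must be positive")
        if self.true_fitness is not None:
            tf = np.asarray(self.true_fitness, dtype=float)
            if tf.size != self.n_strains or not np.all(np.isfinite(tf)):
                raise ValueError("true_fitness must be finite, one per strain")


def _random_spacers(rng: np.random.Generator, n: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        sp = "".join(rng.choice(_BASES, size=20))
        if sp not in seen:
            seen.add(sp)
            out.append(sp)
    return out


def _default_true_fitness(cfg: ScreenSimConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Realistic per-strain doubling numbers under basal-like knockdown:
    controls at exactly D; nonessentials tightly around D; essentials with
    a left tail of fitness defects."""
    D = cfg.doublings
    d = np.empty(cfg.n_strains)
    ess = slice(0, cfg.n_essential)
    non = slice(cfg.n_essential, cfg.n_essential + cfg.n_nonessential)
    ctl = slice(cfg.n_essential + cfg.n_nonessential, cfg.n_strains)
    # essentials: RF mostly near 1, ~half with defects down to RF ~ 0.5
    defect = rng.beta(1.2, 3.0, cfg.n_essential) * 0.5
    has_defect = rng.random(cfg.n_essential) < 0.55
    d[ess] = D * (1.0 - np.where(has_defect, defect, 0.0)
                  + rng.normal(0, 0.004, cfg.n_essential))
    d[non] = D * (1.0 + rng.normal(0, 0.004, cfg.n_nonessential))
    d[ctl] = D
    return d


def simulate_pooled_screen(
    config: ScreenSimConfig,
) -> tuple[SpacerLibrary, SampleCounts, SampleCounts, pd.DataFrame]:
    """Simulate a pooled competition: (library, counts at t0, counts at
    t_end, truth table with per-strain d_i and d_i / D)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    spacers = _random_spacers(rng, cfg.n_strains)
    categories = (["essential"] * cfg.n_essential
                  + ["nonessential"] * cfg.n_nonessential
                  + ["control"] * cfg.n_controls)
    strain_ids = [f"s{i:04d}" for i in range(cfg.n_strains)]
    genes = [f"gene{i:04d}" if c != "control" else f"ctrl{i:04d}"
             for i, c in enumerate(categories)]
    library = SpacerLibrary(pd.DataFrame({
        "strain_id": strain_ids, "spacer": spacers,
        "gene": genes, "category": categories,
    }))

    d = (np.asarray(cfg.true_fitness, dtype=float)
         if cfg.true_fitness is not None
         else _default_true_fitness(cfg, rng))
    a0 = (np.asarray(cfg.t0_abundance, dtype=float)
          if cfg.t0_abundance is not None
          else np.full(cfg.n_strains, 1.0))
    f0 = a0 / a0.sum()
    a1 = a0 * np.exp2(d)
    f1 = a1 / a1.sum()

    def _draw(freqs: np.ndarray) -> np.ndarray:
        if cfg.read_depth is None:
            return freqs * 1e9  # expected counts at a nominal depth
        p = freqs
        if cfg.overdispersion > 0:
            p = rng.dirichlet(freqs / cfg.overdispersion)
        return rng.multinomial(cfg.read_depth, p).astype(float)

    t0 = SampleCounts("t0", "t0", dict(zip(spacers, _draw(f0))))
    t_end = SampleCounts("t_end", "induced", dict(zip(spacers, _draw(f1))))
    truth = pd.DataFrame({
        "strain_id": strain_ids, "category": categories,
        "d_i": d, "rf_true": d / cfg.doublings,
    })
    return library, t0, t_end, truth


def reads_for_counts(counts: SampleCounts, library: SpacerLibrary,
                     read_len: int = 44) -> list[str]:
    """Expand integer spacer counts into read sequences with the spacer
    embedded in a constant scaffold (deterministic order)."""
    reads = []
    for sp in library.spacers:
        c = int(round(counts.counts.get(sp, 0)))
        seq = (SCAFFOLD_5P + sp + SCAFFOLD_3P)[:read_len]
        reads.extend([seq] * c)
    return reads


def write_fastq(path, reads: list[str], quality: str = "I") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")


# ---------------------------------------------------------------------------
# growth curves

@dataclass
class GrowthSimConfig:
    """Forward model of one plate-reader well."""

    mu_max: float = 0.03            # min^-1
    lag_target: float = 60.0        # min; half-max crossing of mu(t)
    od0: float = 0.01
    sample_interval: float = 8.5    # min
    duration: float = 600.0         # min
    noise_sd: float = 0.002         # additive OD noise
    carrying_capacity: float = 1.5  # OD
    ramp_tau: float | None = None   # min; None => max(2, lag_target / 8)
    seed: int = 0

    def __post_init__(self):
        if self.sample_interval <= 0 or self.od0 <= 0 or self.mu_max < 0:
            raise ValueError("invalid growth config")
        if self.duration < 2 * self.sample_interval:
            raise ValueError("duration must cover >= 2 sampling intervals")


def _mu_of_t(t: np.ndarray, cfg: GrowthSimConfig) -> np.ndarray:
    if cfg.lag_target <= 0:
        return np.full_like(np.asarray(t, dtype=float), cfg.mu_max)
    tau = cfg.ramp_tau if cfg.ramp_tau is not None else max(2.0, cfg.lag_target / 8.0)
    return cfg.mu_max / (1.0 + np.exp(-(np.asarray(t, dtype=float)
                                        - cfg.lag_target) / tau))


def simulate_growth_curve(cfg: GrowthSimConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One well's (times, OD): dOD/dt = mu(t) * OD * (1 - OD/K), solved on
    the sampling grid, plus additive Gaussian noise."""
    times = np.arange(0.0, cfg.duration + cfg.sample_interval / 2,
                      cfg.sample_interval)
    sol = solve_ivp(
        lambda t, y: _mu_of_t(t, cfg) * y * (1.0 - y / cfg.carrying_capacity),
        (times[0], times[-1]), [cfg.od0], t_eval=times,
        method="RK45", rtol=1e-8, atol=1e-12,
    )
    od = sol.y[0]
    if cfg.noise_sd > 0:
        rng = rng or np.random.default_rng(cfg.seed)
        od = od + rng.normal(0.0, cfg.noise_sd, od.size)
    return times, od


def simulate_growth_plate(
    config: GrowthSimConfig,
    n_wells: int,
    mu_range: tuple[float, float] | None = None,
    lag_range: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a plate of wells; per-well (mu_max, lag) are drawn uniformly
    from the given ranges (default: every well at the config's values).

    Returns (long-format curves: well, time_min, od; truth: well, mu_max,
    lag, od0).
    """
    rng = np.random.default_rng(config.seed)
    rows, truth_rows = [], []
    for w in range(n_wells):
        mu = (rng.uniform(*mu_range) if mu_range else config.mu_max)
        lag = (rng.uniform(*lag_range) if lag_range else config.lag_target)
        cfg = GrowthSimConfig(
            mu_max=mu, lag_target=lag, od0=config.od0,
            sample_interval=config.sample_interval, duration=config.duration,
            noise_sd=config.noise_sd,
            carrying_capacity=config.carrying_capacity,
            ramp_tau=config.ramp_tau, seed=config.seed,
        )
        times, od = simulate_growth_curve(cfg, rng)
        well = f"w{w:03d}"
        rows.extend((well, t, o) for t, o in zip(times, od))
        truth_rows.append((well, mu, lag, config.od0))
    curves = pd.DataFrame(rows, columns=["well", "time_min", "od"])
    truth = pd.DataFrame(truth_rows, columns=["well", "mu_max", "lag", "od0"])
    return curves, truth


# ---------------------------------------------------------------------------
# cell populations

@dataclass
class CellSimConfig:
    """Forward model of a segmented cell population."""

    n_cells: int = 500
    length_mean: float = 3.0   # um
    length_sd: float = 0.5
    width_mean: float = 1.0    # um
    width_sd: float = 0.05
    contour_points: int = 128
    plate_offsets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"plate1": (0.0, 0.0)})
    pixel_size: float = 0.065  # um/px, typical 100x sCMOS scale
    seed: int = 0

    def __post_init__(self):
        if self.contour_points < 16:
            raise ValueError("contour_points must be >= 16")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def spherocylinder_contour(
    length: float,
    width: float,
    n_points: int = 128,
    center: tuple[float, float] = (0.0, 0.0),
    angle: float = 0.0,
) -> np.ndarray:
    """Contour of a spherocylinder: a (length - width) x width rectangle
    capped by semicircles of diameter width, sampled at n_points equally
    spaced in boundary arc length, rotated by ``angle`` about its center.
    ``length == width`` degenerates to a circle."""
    if width <= 0 or length < width:
        raise ValueError("need width > 0 and length >= width")
    r = width / 2.0
    half = (length - width) / 2.0
    straight = length - width
    perim = 2.0 * straight + 2.0 * np.pi * r
    s = np.linspace(0.0, perim, n_points, endpoint=False)
    pts = np.empty((n_points, 2))
    for i, si in enumerate(s):
        if si < straight:                       # top edge, +x direction
            pts[i] = (-half + si, r)
        elif si < straight + np.pi * r:         # right cap
            th = (si - straight) / r
            pts[i] = (half + r * np.sin(th), r * np.cos(th))
        elif si < 2 * straight + np.pi * r:     # bottom edge, -x direction
            pts[i] = (half - (si - straight - np.pi * r), -r)
        else:                                   # left cap
            th = (si - 2 * straight - np.pi * r) / r
            pts[i] = (-half - r * np.sin(th), -r * np.cos(th))
    c, sn = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -sn], [sn, c]])
    return pts @ rot.T + np.asarray(center)


def simulate_cell_population(
    config: CellSimConfig,
) -> tuple[list[tuple[str, CellContour]], pd.DataFrame]:
    """Simulate cells across plates: list of (plate_id, contour) plus a
    truth table of per-cell (plate, L, W, offsets). Lengths and widths are
    normal draws (resampled while nonpositive or shorter than wide) with
    the plate's additive offsets applied before contour generation."""
    rng = np.random.default_rng(config.seed)
    plates = list(config.plate_offsets.keys())
    cells, rows = [], []
    for i in range(config.n_cells):
        plate = plates[i % len(plates)]
        dl, dw = config.plate_offsets[plate]
        for _ in range(1000):
            L = rng.normal(config.length_mean, config.length_sd) + dl
            W = rng.normal(config.width_mean, config.width_sd) + dw
            if W > 0 and L >= W:
                break
        else:
            raise ValueError("could not draw a valid (length, width) pair")
        angle = rng.uniform(0, np.pi)
        center = rng.uniform(-20, 20, 2)
        verts = spherocylinder_contour(L, W, config.contour_points,
                                       center=tuple(center), angle=angle)
        cid = f"cell{i:05d}"
        cells.append((plate, CellContour(cell_id=cid, vertices=verts)))
        rows.append((cid, plate, L, W, dl, dw))
    truth = pd.DataFrame(rows, columns=[
        "cell_id", "plate_id", "length_um", "width_um",
        "offset_length", "offset_width",
    ])
    return cells, truth


def rasterize_contour(contour: CellContour, pixel_size: float,
                      shape: tuple[int, int] | None = None,
                      origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Scan-fill a contour polygon into a binary mask at pixel_size um/px."""
    from skimage.draw import polygon as draw_polygon

    v = (contour.vertices - np.asarray(origin)) / pixel_size
    if shape is None:
        shape = (int(np.ceil(v[:, 1].max())) + 3, int(np.ceil(v[:, 0].max())) + 3)
    rr, cc = draw_polygon(v[:, 1], v[:, 0], shape)
    mask = np.zeros(shape, dtype=np.uint16)
    mask[rr, cc] = 1
    return mask


# ---------------------------------------------------------------------------
# time lapse

def simulate_time_lapse(
    growth_rate: float,
    frames: int,
    interval: float,
    v0: float = 1.5,
    width: float = 1.0,
    mode: str = "exponential",
    linear_slope: float = 0.01,
    contour_points: int = 128,
) -> tuple[TimeLapseTrack, pd.DataFrame]:
    """A single elongating cell at constant width.

    ``mode="exponential"``: V(t) = v0 * exp(g t); ``mode="linear"``:
    V(t) = v0 + linear_slope * t (um^3/min). Returns the track (contours
    realised as spherocylinders of the implied length) and a truth table
    of per-frame volumes and the rate parameter."""
    if frames < 3:
        raise ValueError("need >= 3 frames")
    t = np.arange(frames) * interval
    if mode == "exponential":
        V = v0 * np.exp(growth_rate * t)
    elif mode == "linear":
        V = v0 + linear_slope * t
    else:
        raise ValueError("mode must be 'exponential' or 'linear'")
    r = width / 2.0
    cap = 4.0 / 3.0 * np.pi * r ** 3
    dims = []
    for k, vk in enumerate(V):
        if vk <= cap:
            raise ValueError("volume below the minimum for this width")
        L = width + (vk - cap) / (np.pi * r ** 2)
        contour = CellContour(
            cell_id="tl_cell", frame=k,
            vertices=spherocylinder_contour(L, width, contour_points),
        )
        dims.append(cell_dimensions(contour))
    track = TimeLapseTrack(cell_id="tl_cell", dims=dims, interval=interval)
    truth = pd.DataFrame({"frame": np.arange(frames), "time_min": t,
                          "volume_um3": V, "growth_rate": growth_rate})
    return track, truth


# ---------------------------------------------------------------------------
# contamination

def simulate_contamination(
    counts: dict[str, SampleCounts],
    mixing: pd.DataFrame,
    read_depth: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, SampleCounts], pd.DataFrame]:
    """Mix per-well reads according to a well x well mixing matrix.

    ``mixing`` rows (destination wells) must sum to 1 over source wells.
    Each destination well's spacer frequencies are the mixture of its
    sources' frequencies; counts are expected values at the source depth,
    or multinomial draws when ``read_depth`` is given. The truth table
    records each well's expected major-contaminant fraction (the largest
    off-diagonal mixing weight resolvable from distinct source spacers)."""
    wells = list(mixing.index)
    if not np.allclose(mixing.sum(axis=1), 1.0):
        raise ValueError("mixing rows must sum to 1")
    rng = np.random.default_rng(seed)
    mixed: dict[str, SampleCounts] = {}
    truth_rows = []
    for dest in wells:
        weights = mixing.loc[dest]
        spacer_freq: dict[str, float] = {}
        for src, wgt in weights.items():
            if wgt == 0:
                continue
            src_counts = counts[src]
            tot = src_counts.total_mapped
            for sp, c in src_counts.counts.items():
                spacer_freq[sp] = spacer_freq.get(sp, 0.0) + wgt * c / tot
        depth = read_depth if read_depth is not None else counts[dest].total_mapped
        spacers = list(spacer_freq)
        freqs = np.array([spacer_freq[s] for s in spacers])
        freqs = freqs / freqs.sum()
        if read_depth is not None:
            vals = rng.multinomial(read_depth, freqs).astype(float)
        else:
            vals = freqs * depth
        mixed[dest] = SampleCounts(dest, counts[dest].condition,
                                   dict(zip(spacers, vals)))
        off = weights.drop(dest, errors="ignore")
        truth_rows.append((dest, float(off.max()) if len(off) else 0.0))
    truth = pd.DataFrame(truth_rows, columns=["well_id", "expected_fraction"])
    return mixed, truth
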