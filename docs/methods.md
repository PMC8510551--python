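# Methods

`phenoscreen` implements the quantitative analysis of an arrayed *E. coli*
CRISPRi essential-gene phenotyping screen: pooled relative fitness from
sgRNA spacer counts, cross-contamination QC, plate-reader growth-curve
features, single-cell contour morphometrics, and robust screen-level
outlier and enrichment statistics. Every stage has a matching forward
model in `phenoscreen.simulate`, so the estimators are validated by
parameter recovery on data with known ground truth.

## Pooled relative fitness

A pooled competition mixes all knockdown strains with nontargeting
controls and grows the pool for D control doublings (default D = 15).
Deep sequencing of the 20-nt sgRNA spacers — each spacer doubles as an
error-free strain barcode — measures each strain's share of the pool
before (t0) and after (t_end). With read-depth-normalised frequencies
f, the per-strain log2 fold change is L_i = log2(f_end,i / f_t0,i), and
relative fitness is

    RF_i = 1 + (L_i − median_ctrl L) / D.

RF is a strain's number of doublings per control doubling: RF = 1 keeps
pace, RF = 0 means no division, and RF < 0 (not clamped) means depletion
faster than dilution. The median-control anchoring makes the control
median exactly 1 per sample pair and cancels pool-composition drift.

Counting is exact substring matching of library spacers in each read;
reads matching no spacer (sequencing errors) or more than one (chimeras)
are tallied separately and excluded. A pseudocount p (default 0.5, the
usual half-count; p = 0 allowed) keeps strains that drop to zero reads
representable. Two consequences are documented rather than hidden: with
p > 0, depth-rescaling invariance of RF holds only approximately (it is
exact at p = 0, where the frequency ratio is scale-free), and at p = 0 a
zero count is an error instead of a very negative L.

Replicates are analysed separately and combined by the mean of RF
(`combine_replicates`).

**Contamination QC.** For an arrayed well, the contamination fraction is
the share of *mapped* reads belonging to the most abundant spacer other
than the expected one; a well is called cross-contaminated when that
fraction strictly exceeds 1e-4. Unmapped reads are excluded from the
denominator — they carry no evidence about which strain they came from.

## Growth-curve features

The instantaneous population growth rate is d ln(OD600)/dt. The log
series is smoothed with a centred moving average (window 5 samples at the
8.5-min cadence; the window shrinks symmetrically at the edges so output
length equals input length). The rate series is then the local
least-squares slope of the smoothed log series over the same window
(Savitzky–Golay, order 1) — a regression slope estimates "the slope of
ln(OD)" with about half the noise variance of a central difference.

μmax is the largest instantaneous rate, with one guard: rate samples are
eligible for the maximum only after the smoothed OD has risen at least
`min_rise` = 0.02 OD units (about 10x a typical plate reader's
shot-to-shot noise) above its starting value. Below that rise the
log-slope is instrument noise, not growth, and an ungated global maximum
systematically inflates μmax for slow-growing wells. The lag time is the
first time the rate series reaches μmax/2, linearly interpolated between
samples; a culture already at half-maximal rate at the first sample has
lag 0.

OD is floored at 1e-4 after optional blank subtraction so noise never
reaches log of a nonpositive value; smoothing of the raw OD instead of
the log is available by flag (`smooth_log=False`).

To control for inoculation effects, each strain's features are
normalised against the median of the k = 10 wild-type replicate wells
with the closest starting OD (ties broken by well order). Normalisation
is a ratio by default; a difference mode is available for references with
near-zero lag.

## Cell morphometrics

**Meshing.** A rod-shaped cell contour is converted to a cell-intrinsic
coordinate system: the poles are the pair of boundary points with maximal
separation; the boundary splits into two pole-to-pole arcs; transverse
ribs pair points across the arcs; the midline is the polyline of rib
midpoints. Starting from arc-length-matched pairs, the midline is relaxed
iteratively — ribs are re-cast along the current midline's normals and the
midline recomputed — with under-relaxation (factor 0.5) and light 1-2-1
smoothing (passes scaling with rib count) to suppress the zigzag
instability of the cap stations. Convergence requires the midline to stop
moving (max displacement < 2e-4 of the pole distance within 40
iterations), every interior rib within 5° of perpendicular to the
midline, a simple (non-self-intersecting) midline, and a midline at least
1.05x longer than the widest rib (the rod-likeness margin). Any failure
raises `RodShapeError`.

**Dimensions.** Length is the pole-to-pole arc length of the midline
(polar caps included). Width is the mean rib width after excluding (a)
ribs whose midline position lies within half the interior median width of
either pole — the cap estimate is refined once — and (b) septal ribs:
contiguous runs where the rib width dips below 75% of the cell's median
rib width, as at the constriction of a dividing cell. Cells that fail to
mesh fall back to the extents along the principal axes of the contour
(`method = "principal_axes"`); a flag can force the fallback for whole
datasets of grossly deformed cells, in which case no width filtering
should be applied downstream.

**Volume** treats the cell as a solid of revolution of the rib-radius
profile about the midline: conical frustums between adjacent ribs, zero
radius at the poles. For a straight spherocylinder this converges to
πr²(L−W) + (4/3)πr³ from below as contour resolution grows (the linear
frustum profile under-cuts the spherical caps); at 256 contour points the
residual is about 1%. The revolution model is an approximation for bent
cells. The principal-axes fallback uses the closed-form spherocylinder
volume of its (L, W), which degenerates correctly to a sphere at L = W.

**Single-cell growth.** The instantaneous single-cell rate is
(1/V) dV/dt: volumes are lightly smoothed (moving average, 3 frames) and
centrally differenced. Exponential volume growth at rate g yields a flat
series at g; linear growth yields a strictly decreasing series — the
signature used to distinguish the two regimes.

**Fluorescence.** Reporter intensity is the background-subtracted sum
over pixels whose centres fall inside the contour polygon, divided by the
polygon area (intensity per unit projected area).

**Aggregation.** Cells with width < 0.6 or > 2.0 μm (strict bounds) are
eliminated as segmentation debris/clumps; strains keep their summaries
only with ≥ 100 surviving cells (under-count is a flag, not an error).
Location is the median; spread is the robust CV, 1.4826·MAD/median.
Plate-to-plate imaging offsets are removed by median centering:
corrected = value − median(plate) + median(global), independently for
length and width, which equalises plate medians exactly and leaves a
single plate unchanged.

**Mask segmentation** (for synthetic raster masks): connected components
not touching the image border are traced with marching squares at the 0.5
level and scaled to μm (y-down raster convention, counterclockwise
contours).

## Screen statistics

Robust location/scale throughout: median, and 1.4826 × MAD as the
Gaussian-consistent robust SD. A strain is an outlier when it lies
strictly beyond k = 3 robust SD of the reference median — nontargeting
controls for fitness (one-sided low), all strains for lag (one-sided
high) and for each dimension (one-sided high). No multiple-testing
correction is applied to these calls; on a Gaussian null the two-sided
flagged fraction converges to 2Φ(−3) ≈ 0.0027. Functional-category
enrichment among flagged strains uses the exact hypergeometric upper tail
P(X ≥ k). Trend lines are fit with an MM-type robust regression: a
high-breakdown Siegel repeated-median start followed by iteratively
reweighted least squares with the redescending Tukey bisquare loss
(tuning constants at the statsmodels defaults; the estimator tolerates
up to ~20% gross outliers). Pearson's r and its two-sided p on the raw
pairs are reported alongside the robust line.

## Synthetic-data generators

The generators emulate the statistical structure the estimators assume,
with truth tables for parameter recovery; fixing the seed fixes every
artifact bit for bit.

* **Pooled screen**: strain abundances evolve as a_i·2^(d_i) where d_i is
  the strain's doubling number while controls complete D = 15; controls
  have d_i = D. Reads are multinomial at the chosen depth (an optional
  Dirichlet overdispersion models library-prep variability; off by
  default — the simplest model consistent with deep sequencing), or exact
  expected counts in the noise-free mode. Default composition 282
  essential / 187 nonessential / 48 controls mirrors a realistic arrayed
  essential-gene library with ~50 nontargeting controls. Default
  per-strain fitness: nonessentials tight around RF = 1, roughly half of
  essentials with defects down to RF ≈ 0.5.
* **Growth curves**: dOD/dt = μ(t)·OD·(1 − OD/K) integrated on the
  8.5-min sampling grid, additive Gaussian OD noise (default 0.002). μ(t)
  ramps logistically from 0 to μmax with its half-max crossing exactly at
  the lag target — the ramp shape is not dictated by the lag definition,
  so it was chosen to make the definition exactly recoverable; the ramp
  timescale is τ = max(2 min, lag/8) (constant μ when lag = 0). od0 =
  0.01 (a typical inoculation density), K = 1.5 OD.
* **Cell populations**: spherocylinder contours (rectangle of length
  L − W capped by semicircles of diameter W), vertices equally spaced in
  boundary arc length, randomly rotated/translated; L, W are normal draws
  (resampled while nonpositive or L < W) with per-plate additive offsets
  applied before generation. Optional rasterisation to binary masks at
  0.065 μm/px (a typical 100x sCMOS scale).
* **Time lapse**: a cell elongating at constant width with V(t) = V0·e^gt
  (or V0 + ct for the linear variant).
* **Contamination**: per-well read mixtures under an explicit well x well
  mixing matrix whose rows sum to 1.

What the generators deliberately do *not* model: phase-contrast optics
and segmentation error beyond rasterisation, pixel-level noise in
fluorescence images, suppressor evolution, plate-position (edge) effects
within a plate, and correlated instrument drift. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise models, not robustness to every artefact of real screens.

## Problem sizes and numerical tolerances

The shipped analyses and tests use desk-scale sizes chosen to exercise
every code path with comfortable statistical margins: a 517-strain screen
at 2 M reads, 50 repeated draws at 1 M reads for bias estimation, a
96-well recovery plate plus 24 wild-type wells, 500-cell morphology
populations, 256-point benchmark contours, and a 10^4-sample Gaussian
null for the outlier false-positive rate. Analytic benchmarks: mesh
dimensions within 1% and volume within 2% of the spherocylinder closed
form; noise-free RF recovery to machine precision; plate-median
equalisation to 1e-12.

## Known limitations

* Exact spacer matching does not tolerate sequencing errors; a 1-mismatch
  read is unmapped by design, so observed depth understates input depth.
* The revolve-the-profile volume overestimates sharply bent cells.
* The meshing pole-finding uses the maximal-separation pair, which can
  misplace poles for cells bent beyond a semicircle; such cells typically
  fail the perpendicularity check and fall back to principal axes.
* The MM-regression tuning constants follow statsmodels defaults; they
  are a documented approximation to high-efficiency MM implementations
  elsewhere and can differ in small-sample efficiency.
* Growth features assume a single growth phase; diauxic curves yield the
  largest of the phase rates and the lag to half of that.
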