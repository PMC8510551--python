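"""Robust screen-level statistics.

All screen-level calls use robust location/scale: the median stands in for
the mean and 1.4826 x MAD (median absolute deviation from the median) for
the standard deviation, so that the handful of true phenotypic outliers the
screen is designed to find do not inflate the null spread they are judged
against. Outliers are strains beyond k robust SDs from a reference median
(k = 3 by default), enrichment of functional categories among flagged
strains is assessed with the exact hypergeometric upper tail, and trend
lines are fit with a high-breakdown redescending M-estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "RobustSummary",
    "OutlierCall",
    "EnrichmentTest",
    "RobustFit",
    "robust_summary",
    "robust_z",
    "call_outliers",
    "hypergeom_enrichment",
    "fit_robust",
    "classify_screen",
]

MAD_TO_SD = 1.4826  # consistency factor for Gaussian data


@dataclass(frozen=True)
class RobustSummary:
    n: int
    median: float
    robust_sd: float  # 1.4826 * MAD


@dataclass(frozen=True)
class OutlierCall:
    strain_id: str
    metric: str
    value: float
    z_robust: float
    flag: str  # "low" | "normal" | "high"


@dataclass(frozen=True)
class EnrichmentTest:
    population: int   # N
    category: int     # K
    selected: int     # n
    overlap: int      # k
    p_value: float    # P(X >= k), X ~ Hypergeom(N, K, n)


@dataclass(frozen=True)
class RobustFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int = 0


def robust_summary(values) -> RobustSummary:
    """Median and MAD-based robust SD of a sample.

    Raises ``ValueError`` on empty input. ``robust_sd`` is zero only when at
    least half the values tie with the median.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("robust_summary: empty input")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return RobustSummary(n=int(x.size), median=med, robust_sd=MAD_TO_SD * mad)


def robust_z(values, reference: RobustSummary) -> np.ndarray:
    if reference.robust_sd <= 0:
        raise ValueError(
            "reference robust_sd is 0 (>=50% ties at the median); "
            "z-scores are undefined -- choose a different reference"
        )
    return (np.asarray(values, dtype=float) - reference.median) / reference.robust_sd


def call_outliers(
    values,
    reference: RobustSummary,
    k: float = 3.0,
    side: str = "both",
    strain_ids=None,
    metric: str = "value",
) -> list[OutlierCall]:
    """Flag values beyond ``k`` robust SDs from a reference median.

    ``side`` selects the tail(s) tested: "both", "low" (only |z| < -k can
    flag) or "high". Inequalities are strict, so a value at exactly k SDs is
    "normal".
    """
    if side not in ("both", "low", "high"):
        raise ValueError(f"side must be both/low/high, got {side!r}")
    z = robust_z(values, reference)
    if strain_ids is None:
        strain_ids = [str(i) for i in range(len(z))]
    calls = []
    for sid, v, zi in zip(strain_ids, np.asarray(values, dtype=float), z):
        flag = "normal"
        if zi < -k and side in ("both", "low"):
            flag = "low"
        elif zi > k and side in ("both", "high"):
            flag = "high"
        calls.append(OutlierCall(str(sid), metric, float(v), float(zi), flag))
    return calls


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentTest:
    """Upper-tail hypergeometric enrichment: P(X >= k) for X ~ HG(N, K, n).

    N strains in the population, K in the category, n selected (flagged),
    k selected strains in the category.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentTest(N, K, n, k, min(p, 1.0))


def _repeated_median_start(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Siegel's repeated-median slope: high-breakdown (50%) start for IRLS
    slope, intercept = sps.siegelslopes(y, x)
    return float(slope), float(intercept)


def fit_robust(x, y) -> RobustFit:
    """Robust line fit: bisquare IRLS from a repeated-median start.

    An MM-type estimator: the high-breakdown Siegel repeated-median line
    seeds iteratively reweighted least squares with the redescending Tukey
    bisquare loss, so up to ~20% gross outliers barely move the slope.
    Pearson's r and its two-sided p are computed on the raw pairs and
    reported alongside, since both are useful to screen readers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("fit_robust requires >= 3 finite points")
    if np.ptp(x) == 0:
        raise ValueError("fit_robust: zero variance in x")
    slope0, icept0 = _repeated_median_start(x, y)
    X = sm.add_constant(x)
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight())
    with warnings.catch_warnings():
        # an exactly collinear (noise-free) input drives the IRLS scale to
        # zero, which statsmodels reports as a convergence warning; the
        # perfect fit is a legitimate answer here
        warnings.simplefilter("ignore")
        res = rlm.fit(start_params=np.array([icept0, slope0]))
    r, p = sps.pearsonr(x, y)
    return RobustFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        pearson_r=float(r),
        p_value=float(p),
        n=int(x.size),
    )


@dataclass
class ScreenClassification:
    """Per-strain flags plus screen-level counts and category enrichments."""

    fitness_calls: pd.DataFrame | None = None
    lag_calls: pd.DataFrame | None = None
    morphology_calls: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)
    enrichments: pd.DataFrame | None = None

    def summary_text(self) -> str:
        lines = ["screen classification summary", "-" * 30]
        for key, val in self.counts.items():
            lines.append(f"{key}: {val}")
        if self.enrichments is not None and len(self.enrichments):
            lines.append("")
            lines.append("category enrichments (hypergeometric upper tail):")
            for _, row in self.enrichments.iterrows():
                lines.append(
                    f"  {row['flag_set']} x {row['group']}: "
                    f"k={row['overlap']}/{row['selected']} of K={row['category']}"
                    f"/N={row['population']}, p={row['p_value']:.3g}"
                )
        return "\n".join(lines) + "\n"


def _calls_frame(calls: list[OutlierCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.strain_id, c.metric, c.value, c.z_robust, c.flag) for c in calls],
        columns=["strain_id", "metric", "value", "z_robust", "flag"],
    )


def classify_screen(
    annotations: pd.DataFrame,
    fitness: pd.DataFrame | None = None,
    growth: pd.DataFrame | None = None,
    morphology: pd.DataFrame | None = None,
    k: float = 3.0,
    enrichment_groups: str | None = "group",
) -> ScreenClassification:
    """Apply the robust k-SD classifiers to per-strain screen tables.

    ``annotations`` must carry ``strain_id`` and ``category`` (essential /
    nonessential / control) and may carry a functional ``group`` column for
    enrichment testing. References follow the screen's conventions:

    * fitness (column ``rf``): one-sided low, reference = nontargeting
      controls;
    * lag (column ``lag_norm``): one-sided high, reference = all strains;
    * morphology (columns ``corrected_length``/``corrected_width``):
      one-sided high per dimension, reference = all strains.

    Strains missing from ``annotations`` are dropped with a warning column
    rather than an error.
    """
    ann = annotations.set_index("strain_id")
    out = ScreenClassification()
    flag_sets: dict[str, set[str]] = {}

    if fitness is not None and len(fitness):
        fit = fitness[fitness["strain_id"].isin(ann.index)].copy()
        ctrl = fit.loc[
            ann.loc[fit["strain_id"], "category"].values == "control", "rf"
        ]
        if ctrl.empty:
            raise ValueError("classify_screen: no control strains in fitness table")
        ref = robust_summary(ctrl)
        calls = _calls_frame(
            call_outliers(fit["rf"].values, ref, k=k, side="low",
                          strain_ids=fit["strain_id"], metric="rf")
        )
        calls["category"] = ann.loc[calls["strain_id"], "category"].values
        out.fitness_calls = calls
        defect = calls["flag"] == "low"
        for cat in ("essential", "nonessential"):
            in_cat = calls["category"] == cat
            out.counts[f"fitness_defect_{cat}"] = int((defect & in_cat).sum())
            out.counts[f"n_{cat}"] = int(in_cat.sum())
        flag_sets["fitness_defect"] = set(calls.loc[defect, "strain_id"])

    if growth is not None and len(growth):
        gr = growth[growth["strain_id"].isin(ann.index)].copy()
        ref = robust_summary(gr["lag_norm"])
        calls = _calls_frame(
            call_outliers(gr["lag_norm"].values, ref, k=k, side="high",
                          strain_ids=gr["strain_id"], metric="lag_norm")
        )
        out.lag_calls = calls
        long_lag = calls["flag"] == "high"
        out.counts["long_lag"] = int(long_lag.sum())
        flag_sets["long_lag"] = set(calls.loc[long_lag, "strain_id"])

    if morphology is not None and len(morphology):
        mo = morphology[morphology["strain_id"].isin(ann.index)].copy()
        frames = []
        for dim, col in (("length", "corrected_length"),
                         ("width", "corrected_width")):
            ref = robust_summary(mo[col])
            if ref.robust_sd <= 0:
                # degenerate reference (e.g. one strain per plate, where
                # plate correction collapses every value onto the global
                # median): outlier calls are undefined for this metric
                warnings.warn(f"classify_screen: zero robust spread in "
                              f"{col}; skipping morphology calls")
                frames = []
                break
            frames.append(_calls_frame(
                call_outliers(mo[col].values, ref, k=k, side="high",
                              strain_ids=mo["strain_id"], metric=col)
            ))
        if frames:
            out.morphology_calls = pd.concat(frames, ignore_index=True)
            longer = set(frames[0].loc[frames[0]["flag"] == "high",
                                       "strain_id"])
            wider = set(frames[1].loc[frames[1]["flag"] == "high",
                                      "strain_id"])
            out.counts["longer"] = len(longer)
            out.counts["wider"] = len(wider)
            out.counts["long_and_wide"] = len(longer & wider)
            flag_sets["longer"] = longer
            flag_sets["wider"] = wider

    if enrichment_groups and enrichment_groups in annotations.columns and flag_sets:
        rows = []
        tested = ann[ann[enrichment_groups].notna()]
        for set_name, flagged in flag_sets.items():
            pop = set(tested.index)
            n_sel = len(flagged & pop)
            for grp, members in tested.groupby(enrichment_groups).groups.items():
                K = len(set(members) & pop)
                kk = len(flagged & set(members))
                if K == 0:
                    continue
                test = hypergeom_enrichment(len(pop), K, n_sel, kk)
                rows.append((set_name, grp, test.population, test.category,
                             test.selected, test.overlap, test.p_value))
        out.enrichments = pd.DataFrame(
            rows, columns=["flag_set", "group", "population", "category",
                           "selected", "overlap", "p_value"],
        )
    return out
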