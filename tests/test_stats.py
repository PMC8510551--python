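"""Robust summaries, outlier calls, enrichment, robust regression,
and the screen-level classifier."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoscreen.stats import (
    call_outliers,
    classify_screen,
    fit_robust,
    hypergeom_enrichment,
    robust_summary,
)


def hypergeom_upper_tail_enum(N, K, n, k):
    """Independent oracle: exact combinatorial summation of P(X >= k)."""
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / comb(N, n)


class TestRobustSummary:
    def test_hand_example_with_gross_outlier(self):
        rs = robust_summary([1, 2, 3, 4, 100])
        assert rs.median == 3.0
        assert rs.robust_sd == pytest.approx(1.4826)

    def test_constant_vector_zero_spread(self):
        assert robust_summary([5.0] * 7).robust_sd == 0.0

    def test_consistency_with_gaussian_sd(self):
        rng = np.random.default_rng(1)
        rs = robust_summary(rng.standard_normal(100_000))
        assert rs.robust_sd == pytest.approx(1.0, abs=0.02)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            robust_summary([])

    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 100))
    @settings(max_examples=30, deadline=None)
    def test_affine_equivariance(self, shift, scale):
        x = np.array([0.3, -1.2, 2.8, 0.9, -0.4, 1.7])
        a, b = robust_summary(x), robust_summary(scale * x + shift)
        assert b.median == pytest.approx(scale * a.median + shift, abs=1e-9)
        assert b.robust_sd == pytest.approx(scale * a.robust_sd, rel=1e-9)

    def test_permutation_invariance(self):
        x = [4.0, 1.0, 7.0, 2.0, 9.0]
        a, b = robust_summary(x), robust_summary(sorted(x))
        assert (a.median, a.robust_sd) == (b.median, b.robust_sd)


class TestCallOutliers:
    def test_beyond_three_sd_flagged_low(self):
        ref = robust_summary([0, 1, 2, 3, 4])
        calls = call_outliers([ref.median - 3.1 * ref.robust_sd], ref)
        assert calls[0].flag == "low"

    def test_exactly_three_sd_is_normal(self):
        ref = robust_summary([0, 1, 2, 3, 4])
        calls = call_outliers([ref.median - 3.0 * ref.robust_sd], ref)
        assert calls[0].flag == "normal"

    def test_one_sided_high_ignores_low_tail(self):
        ref = robust_summary([0, 1, 2, 3, 4])
        calls = call_outliers([ref.median - 10 * ref.robust_sd], ref,
                              side="high")
        assert calls[0].flag == "normal"

    def test_gaussian_null_false_positive_rate(self):
        # two-sided flagged fraction converges to 2 * Phi(-3) = 0.0027
        rng = np.random.default_rng(12)
        x = rng.standard_normal(10_000)
        calls = call_outliers(x, robust_summary(x))
        frac = np.mean([c.flag != "normal" for c in calls])
        assert frac == pytest.approx(0.0027, abs=0.002)

    def test_zero_spread_reference_raises(self):
        with pytest.raises(ValueError, match="robust_sd"):
            call_outliers([1.0], robust_summary([2.0] * 5))


class TestHypergeomEnrichment:
    def test_worked_example(self):
        t = hypergeom_enrichment(10, 4, 5, 4)
        assert t.p_value == pytest.approx(6 / 252, rel=1e-12)

    def test_zero_overlap_certain(self):
        assert hypergeom_enrichment(20, 5, 6, 0).p_value == pytest.approx(1.0)

    def test_saturated_draw_certain(self):
        assert hypergeom_enrichment(8, 8, 8, 8).p_value == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_instances(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        expected = hypergeom_upper_tail_enum(N, K, n, k)
                        got = hypergeom_enrichment(N, K, n, k).p_value
                        assert got == pytest.approx(expected, rel=1e-9), \
                            (N, K, n, k)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 4, 5, 5)


class TestFitRobust:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        fit = fit_robust(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, rel=1e-6)
        assert fit.intercept == pytest.approx(1.0, abs=1e-6)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_single_gross_outlier_resistance(self):
        # outlier near the end of the x range, where leverage on the
        # ordinary least-squares slope is largest
        x = np.linspace(0, 10, 50)
        y = 2 * x + 1
        y[46] += 200.0
        fit = fit_robust(x, y)
        assert fit.slope == pytest.approx(2.0, rel=0.02)
        # ordinary least squares, by contrast, is pulled off the line
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(ols_slope - 2.0) > 0.1

    def test_breakdown_with_20_percent_outliers(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 100)
        y = 3 * x - 2 + rng.normal(0, 0.1, 100)
        bad = rng.choice(100, 20, replace=False)
        y[bad] += rng.uniform(30, 60, 20)
        fit = fit_robust(x, y)
        assert fit.slope == pytest.approx(3.0, rel=0.05)

    def test_null_correlation_near_zero(self):
        rng = np.random.default_rng(8)
        x = rng.permutation(1000).astype(float)
        y = rng.standard_normal(1000)
        fit = fit_robust(x, y)
        assert abs(fit.pearson_r) < 0.1

    def test_degenerate_x_raises(self):
        with pytest.raises(ValueError, match="variance"):
            fit_robust([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassifyScreen:
    def _annotations(self, n, n_ctrl, group_every=0):
        rows = []
        for i in range(n):
            cat = ("control" if i < n_ctrl
                   else "essential" if i % 2 else "nonessential")
            grp = "membrane" if group_every and i % group_every == 0 else None
            rows.append((f"s{i}", cat, grp))
        return pd.DataFrame(rows, columns=["strain_id", "category", "group"])

    def test_planted_fitness_outliers_exactly_recovered(self):
        rng = np.random.default_rng(3)
        ann = self._annotations(60, 10)
        rf = 1.0 + rng.normal(0, 0.01, 60)
        rf[15], rf[30] = 0.6, 0.5  # planted 4+ SD defects
        fitness = pd.DataFrame({"strain_id": ann["strain_id"], "rf": rf})
        out = classify_screen(ann, fitness=fitness)
        flagged = set(out.fitness_calls.loc[
            out.fitness_calls["flag"] == "low", "strain_id"])
        assert flagged == {"s15", "s30"}

    def test_identical_values_no_outliers(self):
        ann = self._annotations(40, 8)
        rng = np.random.default_rng(4)
        # controls get tiny jitter so the reference spread is nonzero
        rf = np.ones(40) + np.where(np.arange(40) < 8,
                                    rng.normal(0, 1e-3, 40), 0.0)
        fitness = pd.DataFrame({"strain_id": ann["strain_id"], "rf": rf})
        out = classify_screen(ann, fitness=fitness)
        assert out.counts["fitness_defect_essential"] == 0
        assert out.counts["fitness_defect_nonessential"] == 0

    def test_planted_category_enrichment_matches_enumeration(self):
        # all 5 flagged wide strains drawn from a 5-member category of N=50
        rng = np.random.default_rng(6)
        ann = pd.DataFrame({
            "strain_id": [f"s{i}" for i in range(50)],
            "category": ["essential"] * 50,
            "group": ["eca" if i < 5 else "other" for i in range(50)],
        })
        width = 1.0 + rng.normal(0, 0.005, 50)
        width[:5] += 0.5
        morph = pd.DataFrame({
            "strain_id": ann["strain_id"],
            "corrected_length": np.full(50, 3.0) + rng.normal(0, 0.005, 50),
            "corrected_width": width,
        })
        out = classify_screen(ann, morphology=morph)
        assert out.counts["wider"] == 5
        row = out.enrichments.query("flag_set == 'wider' and group == 'eca'")
        expected = hypergeom_upper_tail_enum(50, 5, 5, 5)
        assert float(row["p_value"].iloc[0]) == pytest.approx(expected,
                                                              rel=1e-9)

    def test_unannotated_strains_are_dropped(self):
        ann = self._annotations(20, 5)
        fitness = pd.DataFrame({
            "strain_id": [f"s{i}" for i in range(25)],
            "rf": 1.0 + np.linspace(-0.005, 0.005, 25),
        })
        out = classify_screen(ann, fitness=fitness)
        assert len(out.fitness_calls) == 20
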