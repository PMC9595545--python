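import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from hypothesis import given, settings, strategies as st

from fragscan.config import AnalysisConfig
from fragscan.cooccurrence import (
    benjamini_hochberg,
    chi_square_2x2,
    distance_distribution,
    mann_whitney_u,
    nearest_pair_gap,
    proximity_summary,
    summarize_window_contrast,
    two_sample_t,
)
from fragscan.motif_scan import CPG_COLUMNS, HIT_COLUMNS
from fragscan.window_analysis import WindowClassification

from conftest import breakpoint_table


def hits_frame(rows):
    """rows: (chrom, start[, mismatches])."""
    return pd.DataFrame(
        [
            {
                "chrom": r[0], "start": r[1], "end": r[1] + 9, "strand": "+",
                "mismatches": r[2] if len(r) > 2 else 0, "seq": "ACAAAAACC",
            }
            for r in rows
        ],
        columns=list(HIT_COLUMNS),
    )


def cpgs_frame(rows):
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": s + 2} for c, s in rows],
        columns=list(CPG_COLUMNS),
    )


class TestProximity:
    def test_both_features_within_radius(self):
        s = proximity_summary(
            breakpoint_table([("c", 500)]),
            hits_frame([("c", 450)]), cpgs_frame([("c", 520)]), 100,
        )
        assert (s.n_with_nonamer, s.n_with_cpg, s.n_with_both) == (1, 1, 1)

    def test_nonamer_beyond_radius(self):
        s = proximity_summary(
            breakpoint_table([("c", 500)]), hits_frame([("c", 650)]),
            cpgs_frame([]), 100,
        )
        assert s.n_with_nonamer == 0

    def test_overlap_is_inclusive_at_edges(self):
        # context [400, 601); feature [392, 401) overlaps by one base
        s = proximity_summary(
            breakpoint_table([("c", 500)]), hits_frame([("c", 392)]),
            cpgs_frame([]), 100,
        )
        assert s.n_with_nonamer == 1
        s = proximity_summary(
            breakpoint_table([("c", 500)]), hits_frame([("c", 391)]),
            cpgs_frame([]), 100,
        )
        assert s.n_with_nonamer == 0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_translation_invariance(self, shift):
        def build(offset):
            return (
                breakpoint_table([("c", 500 + offset), ("c", 900 + offset)]),
                hits_frame([("c", 450 + offset), ("c", 2000 + offset)]),
                cpgs_frame([("c", 540 + offset)]),
            )
        base = proximity_summary(*build(0), 100)
        moved = proximity_summary(*build(shift), 100)
        assert base.to_dict() == moved.to_dict()


class TestNearestPairGap:
    def test_disjoint_gap(self):
        g = nearest_pair_gap(
            "c", 20, hits_frame([("c", 20)]), cpgs_frame([("c", 10)]), 100
        )
        assert g == 8  # CpG [10,12) to nonamer [20,29)

    def test_overlap_gap_zero(self):
        g = nearest_pair_gap(
            "c", 10, hits_frame([("c", 5)]), cpgs_frame([("c", 10)]), 100
        )
        assert g == 0

    def test_no_cpg_within_radius(self):
        g = nearest_pair_gap(
            "c", 500, hits_frame([("c", 500)]), cpgs_frame([("c", 5000)]), 100
        )
        assert g is None

    def test_symmetric_in_feature_order(self):
        # CpG left of nonamer: [40,42) to [60,69) -> 18
        left = nearest_pair_gap(
            "c", 50, hits_frame([("c", 60)]), cpgs_frame([("c", 40)]), 100
        )
        assert left == 18
        mirrored = nearest_pair_gap(
            "c", 50, hits_frame([("c", 30)]), cpgs_frame([("c", 57)]), 100
        )
        assert mirrored == 57 - 39  # nonamer [30,39) then CpG [57,59)

    def test_mismatch_class_restriction(self):
        hits = hits_frame([("c", 20, 2), ("c", 40, 4)])
        cpgs = cpgs_frame([("c", 10)])
        assert nearest_pair_gap("c", 20, hits, cpgs, 100, mismatch=2) == 8
        assert nearest_pair_gap("c", 20, hits, cpgs, 100, mismatch=4) == 40 - 12
        assert nearest_pair_gap("c", 20, hits, cpgs, 100, mismatch=3) is None


class TestDistanceDistribution:
    def test_empty_flagged(self, default_config):
        summary = distance_distribution(
            breakpoint_table([("c", 100)]), hits_frame([]), cpgs_frame([]),
            default_config,
        )
        assert summary.empty
        assert np.isnan(summary.median)

    def test_per_break_minimal_gap(self, default_config):
        summary = distance_distribution(
            breakpoint_table([("c", 50)]),
            hits_frame([("c", 60), ("c", 90)]), cpgs_frame([("c", 40)]),
            default_config,
        )
        assert summary.per_break["gap"].tolist() == [18]
        assert summary.fraction_within_gap_max == 1.0


class TestChiSquare:
    def test_independence_zero(self):
        stat, p, df = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0 and df == 1

    def test_hand_checked_value(self):
        stat, _, _ = chi_square_2x2([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3, abs=1e-12)

    def test_diagonal_table(self):
        stat, _, _ = chi_square_2x2([[5, 0], [0, 5]])
        assert stat == pytest.approx(10.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_yates_reduces_statistic(self):
        plain, _, _ = chi_square_2x2([[20, 10], [10, 20]])
        corrected, _, _ = chi_square_2x2([[20, 10], [10, 20]], yates=True)
        assert corrected < plain

    def test_matches_scipy_on_random_tables(self, rng):
        """Independent cross-check of the closed form against scipy."""
        for _ in range(300):
            t = rng.integers(1, 60, size=(2, 2))
            stat, p, _ = chi_square_2x2(t)
            s_stat, s_p, _, _ = sps.chi2_contingency(t, correction=False)
            assert stat == pytest.approx(s_stat, abs=1e-9)
            assert p == pytest.approx(s_p, abs=1e-9)
            y_stat, y_p, _ = chi_square_2x2(t, yates=True)
            sy_stat, sy_p, _, _ = sps.chi2_contingency(t, correction=True)
            assert y_stat == pytest.approx(sy_stat, abs=1e-9)
            assert y_p == pytest.approx(sy_p, abs=1e-9)

    def test_p_monotone_in_statistic(self):
        stats_ps = [chi_square_2x2([[20 + k, 10], [10, 20]])[:2] for k in range(10)]
        stats, ps = zip(*stats_ps)
        assert list(stats) == sorted(stats)
        assert list(ps) == sorted(ps, reverse=True)


class TestMannWhitney:
    def test_separated_samples(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_midrank(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2

    def test_single_tie(self):
        u, p = mann_whitney_u([5], [5])
        assert u == 0.5 and p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])

    def test_matches_scipy_asymptotic(self, rng):
        for _ in range(100):
            x = rng.integers(0, 12, size=rng.integers(3, 30))
            y = rng.integers(0, 12, size=rng.integers(3, 30))
            u, p = mann_whitney_u(x, y)
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert u == pytest.approx(res.statistic)
            assert p == pytest.approx(res.pvalue, abs=1e-10)


class TestTTest:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        t, p, _ = two_sample_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_guard(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_t([1, 1, 1, 1], [2, 2, 2, 2])

    def test_power_on_separated_normals(self, rng):
        """N(0,1) vs N(1,1), n=50: near-certain rejection at alpha=.05."""
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(0, 1, 50)
            y = rng.normal(1, 1, 50)
            _, p, _ = two_sample_t(x, y)
            rejections += p < 0.05
        assert rejections / reps > 0.99

    def test_welch_vs_pooled_df(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 3, 40)
        _, _, df_w = two_sample_t(x, y, welch=True)
        _, _, df_p = two_sample_t(x, y, welch=False)
        assert df_p == 48 and df_w < 48


class TestBH:
    def test_monotone_and_bounded(self):
        p = [0.01, 0.04, 0.03, 0.9]
        adj = benjamini_hochberg(p)
        assert (adj >= np.array(p) - 1e-15).all()
        assert (adj <= 1).all()
        np.testing.assert_allclose(adj, [0.04, 0.053333, 0.053333, 0.9], atol=1e-4)


def _window_stats(n, n_nonamers, n_breaks, has_pair_frac, rng, gc=0.5):
    return pd.DataFrame(
        {
            "chrom": "c",
            "start": np.arange(n) * 100,
            "end": (np.arange(n) + 1) * 100,
            "full": True,
            "n_breaks": n_breaks,
            "n_nonamers": rng.poisson(n_nonamers, n),
            "n_cpgs": rng.poisson(1.0, n),
            "gc": gc,
            "has_cpg": rng.random(n) < 0.7,
            "has_pair": rng.random(n) < has_pair_frac,
        }
    )


class TestWindowContrast:
    def test_null_case_behaves(self, rng):
        broken = _window_stats(50, 3, 3, 0.5, rng)
        unbroken = _window_stats(500, 3, 0, 0.5, rng)
        cls = WindowClassification(broken, unbroken, unbroken.iloc[:0], 3)
        rep = summarize_window_contrast(cls)
        assert abs(rep["broken"]["mean_nonamers"] - rep["unbroken"]["mean_nonamers"]) < 1.0
        assert rep["chi_square"]["p"] > 1e-4

    def test_reports_class_sizes(self, rng):
        broken = _window_stats(39, 8, 4, 0.9, rng)
        controls = _window_stats(39, 1, 0, 0.3, rng)
        cls = WindowClassification(broken, controls, controls.iloc[:0], 3)
        rep = summarize_window_contrast(cls, controls=controls)
        assert rep["broken"]["n_windows"] == 39
        assert rep["unbroken"]["n_windows"] == 39

    def test_empty_class_rejected(self, rng):
        broken = _window_stats(5, 8, 4, 0.9, rng)
        cls = WindowClassification(broken, broken.iloc[:0], broken.iloc[:0], 3)
        with pytest.raises(ValueError):
            summarize_window_contrast(cls)
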