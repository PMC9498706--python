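"""Enrichment statistics: Z-test, fold formulas, hypergeometric test,
window scan and stratification."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest

import g4clock as g4
from g4clock.enrichment import hypergeom_upper_tail


def hypergeom_enumeration(n_obs, N, K, n_draws) -> float:
    """Exact upper tail by enumeration (integer arithmetic)."""
    total = Fraction(0)
    for k in range(max(n_obs, 0), min(K, n_draws) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n_draws - k), comb(N, n_draws))
    return float(total)


class TestZTest:
    def test_closed_form_example(self):
        z, p = g4.z_test_upper(14, [8, 10, 12])
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.0227501, abs=1e-6)

    def test_at_the_mean_p_half(self):
        z, p = g4.z_test_upper(10, [8, 10, 12])
        assert z == 0.0 and p == pytest.approx(0.5)

    def test_degenerate_sd_step_rule(self):
        with pytest.warns(RuntimeWarning):
            _, p_hi = g4.z_test_upper(5, [3, 3, 3])
        assert p_hi == 0.0
        with pytest.warns(RuntimeWarning):
            _, p_lo = g4.z_test_upper(2, [3, 3, 3])
        assert p_lo == 1.0
        with pytest.warns(RuntimeWarning):
            _, p_eq = g4.z_test_upper(3, [3, 3, 3])
        assert p_eq == 1.0

    def test_too_few_counts_rejected(self):
        with pytest.raises(ValueError):
            g4.z_test_upper(5, [3])


class TestShuffleEnrichment:
    @pytest.fixture
    def sizes(self):
        return g4.ChromSizes({"chr1": 50_000})

    def test_fold_formula_holds_exactly(self, sizes):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(49_000, size=100, replace=False))
        g4s = g4.IntervalSet.from_arrays(
            {"chr1": (starts, starts + 40)}, sizes
        )
        clock = [g4.ClockCpG("chr1", int(p)) for p in range(1_000, 40_000, 2_000)]
        res = g4.ShuffleEnrichment.from_clock(
            g4s, clock, 500, sizes, g4.ShuffleConfig(n_shuffles=10, seed=3)
        ).fit()
        assert res.F == res.c / (1.0 + res.t)
        assert res.t == pytest.approx(res.shuffle_counts.mean())
        assert res.n_shuffles == len(res.shuffle_counts) == 10
        assert 0.0 <= res.p <= 1.0

    def test_fold_uses_one_plus_t_denominator(self):
        # c = 60 against a shuffle mean of 19 gives F = 60 / 20 = 3
        counts = np.array([17, 19, 21])
        c = 60
        F = c / (1.0 + counts.mean())
        assert F == pytest.approx(3.0)

    def test_empty_inputs_degenerate(self, sizes):
        empty = g4.IntervalSet.from_arrays({}, sizes)
        t = g4.IntervalSet.from_arrays(
            {"chr1": (np.array([0]), np.array([100]))}, sizes
        )
        with pytest.warns(RuntimeWarning):
            res = g4.enrich_vs_shuffle(empty, t, sizes, g4.ShuffleConfig(seed=0))
        assert res.c == 0 and res.F == 0.0 and res.p == 1.0
        assert res.empty_inputs

    def test_zero_overlap_gives_zero_fold(self, sizes):
        g4s = g4.IntervalSet.from_arrays(
            {"chr1": (np.array([0]), np.array([10]))}, sizes
        )
        targets = g4.IntervalSet.from_arrays(
            {"chr1": (np.array([40_000]), np.array([40_100]))}, sizes
        )
        with pytest.warns(RuntimeWarning, match="sd = 0"):
            res = g4.enrich_vs_shuffle(
                g4s, targets, sizes, g4.ShuffleConfig(n_shuffles=5, seed=0)
            )
        assert res.c == 0 and res.F == 0.0

    def test_observed_overlap_monotone_in_g4s(self, sizes):
        targets = g4.IntervalSet.from_arrays(
            {"chr1": (np.array([1_000]), np.array([2_000]))}, sizes
        )
        small = g4.IntervalSet.from_arrays(
            {"chr1": (np.array([1_100]), np.array([1_150]))}, sizes
        )
        bigger = g4.IntervalSet.from_arrays(
            {"chr1": (np.array([1_100, 1_500]), np.array([1_150, 1_540]))},
            sizes,
        )
        import warnings as _warnings

        cfg = g4.ShuffleConfig(n_shuffles=5, seed=1)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # sparse toy data
            r_small = g4.enrich_vs_shuffle(small, targets, sizes, cfg)
            r_big = g4.enrich_vs_shuffle(bigger, targets, sizes, cfg)
        assert r_big.c >= r_small.c

    def test_protein_site_enrichment_self_overlap(self, sizes):
        starts = np.arange(10) * 1_000
        peaks = g4.IntervalSet.from_arrays(
            {"chr1": (starts, starts + 50)}, sizes
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # sparse toy data
            res = g4.protein_site_enrichment(
                peaks, peaks, sizes, g4.ShuffleConfig(n_shuffles=10, seed=2)
            )
        # a sparse set fully overlapping itself is strongly enriched
        assert res.c == peaks.total_bp
        assert res.F > 10
        assert res.significant


class TestGlobalCpGEnrichment:
    def make_inputs(self, N=100, K=20, n_clock=10, n_obs=5):
        """Deterministic construction achieving exact N, K, n_obs counts.

        CpGs sit 100 bp apart; the first K have a G4 on top of them; the
        clock takes n_obs CpGs from the covered block and the rest from
        the uncovered block.
        """
        sizes = g4.ChromSizes({"chr1": 100 * (N + 1)})
        positions = (np.arange(N) + 1) * 100
        catalog = g4.CpGCatalog({"chr1": positions})
        g4s = g4.IntervalSet.from_arrays(
            {"chr1": (positions[:K], positions[:K] + 2)}, sizes
        )
        clock = [g4.ClockCpG("chr1", int(p), 1.0) for p in positions[:n_obs]]
        clock += [
            g4.ClockCpG("chr1", int(p), 1.0)
            for p in positions[K : K + (n_clock - n_obs)]
        ]
        return g4s, clock, catalog

    def test_counts_and_fold(self):
        g4s, clock, catalog = self.make_inputs()
        res = g4.enrich_vs_global_cpg(g4s, clock, catalog, window=0)
        assert (res.N, res.K, res.n_clock, res.n_obs) == (100, 20, 10, 5)
        assert res.f == pytest.approx(0.2)
        assert res.expected == pytest.approx(2.0)
        assert res.fold == pytest.approx(2.5)

    def test_p_matches_enumeration(self):
        g4s, clock, catalog = self.make_inputs()
        res = g4.enrich_vs_global_cpg(g4s, clock, catalog, window=0)
        assert res.p == pytest.approx(0.0254645464270431, abs=1e-12)
        assert res.p == pytest.approx(
            hypergeom_enumeration(5, 100, 20, 10), abs=1e-12
        )

    def test_zero_observed(self):
        g4s, clock, catalog = self.make_inputs(n_obs=0)
        res = g4.enrich_vs_global_cpg(g4s, clock, catalog, window=0)
        assert res.n_obs == 0 and res.fold == 0.0 and res.p == 1.0

    def test_absent_clock_cpgs_warn(self):
        g4s, clock, catalog = self.make_inputs()
        clock = clock + [g4.ClockCpG("chr1", 33, 1.0)]  # not a catalog CpG
        with pytest.warns(RuntimeWarning, match="absent|not in"):
            res = g4.enrich_vs_global_cpg(g4s, clock, catalog, window=0)
        assert res.n_absent == 1

    def test_log_tail_finite_below_underflow(self):
        # far-tail parameters underflow linear p but keep a finite log10
        p, log10_p = hypergeom_upper_tail(950, 100_000, 1_000, 1_000)
        assert p == 0.0
        assert math.isfinite(log10_p) and log10_p < -300


class TestStratify:
    def test_partition_by_sign(self):
        clock = [
            g4.ClockCpG("chr1", 10, +0.5),
            g4.ClockCpG("chr1", 20, -0.2),
            g4.ClockCpG("chr1", 30, +0.1),
        ]
        strata = g4.stratify_by_direction(clock)
        assert len(strata.hyper) == 2 and len(strata.hypo) == 1
        assert strata.n_zero == 0

    def test_all_positive_leaves_hypo_empty(self):
        clock = [g4.ClockCpG("chr1", i, 1.0) for i in range(5)]
        strata = g4.stratify_by_direction(clock)
        assert strata.hypo == [] and len(strata.hyper) == 5

    def test_zero_direction_excluded_with_count(self):
        clock = [g4.ClockCpG("chr1", 10, 0.0), g4.ClockCpG("chr1", 20, -1.0)]
        with pytest.warns(RuntimeWarning):
            strata = g4.stratify_by_direction(clock)
        assert strata.n_zero == 1
        assert len(strata.hyper) + len(strata.hypo) == 1


class TestWindowScan:
    def test_grid_validation(self, small_scenario):
        sc = small_scenario
        with pytest.raises(ValueError):
            g4.window_scan(sc.g4s, sc.clock, sc.chrom_sizes, windows=[100, 100])
        with pytest.raises(ValueError):
            g4.window_scan(sc.g4s, sc.clock, sc.chrom_sizes, windows=[1000, 10])
        with pytest.raises(ValueError):
            g4.window_scan(sc.g4s, sc.clock, sc.chrom_sizes, windows=[])

    def test_single_window_scan(self, small_scenario):
        sc = small_scenario
        scan = g4.window_scan(
            sc.g4s, sc.clock, sc.chrom_sizes, catalog=sc.catalog,
            windows=[1000], config=g4.ShuffleConfig(n_shuffles=10, seed=0),
        )
        assert scan.windows == [1000]
        assert len(scan.shuffle_results) == len(scan.cpg_results) == 1
        df = scan.to_frame()
        assert {"window", "F", "fold_cpg", "p_shuffle", "p_cpg"} <= set(df.columns)
        assert "max F at window" in scan.summary()

    def test_plot_returns_axes(self, small_scenario):
        mpl = pytest.importorskip("matplotlib")
        mpl.use("Agg")
        sc = small_scenario
        scan = g4.window_scan(
            sc.g4s, sc.clock, sc.chrom_sizes, windows=[100, 1000],
            config=g4.ShuffleConfig(n_shuffles=2, seed=0),
        )
        ax = scan.plot()
        assert ax.get_xlabel() == "window size (bp)"

    def test_planted_scenario_recovers_fold(self, small_scenario):
        """On the planted scenario both statistics at window 2d sit near
        the analytic expectation (looser band than acceptance: small genome)."""
        sc = small_scenario
        truth_fold = sc.truth.true_fold_estimate()
        scan = g4.window_scan(
            sc.g4s, sc.clock, sc.chrom_sizes, catalog=sc.catalog,
            windows=[1000], config=g4.ShuffleConfig(n_shuffles=15, seed=0),
        )
        F = scan.shuffle_results[0].F
        fold = scan.cpg_results[0].fold
        assert F == pytest.approx(truth_fold, rel=0.25)
        assert fold == pytest.approx(truth_fold, rel=0.25)
        assert scan.shuffle_results[0].significant
        assert scan.cpg_results[0].significant
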