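"""Differential track, SG smoothing, FDR calibration, locus calling, t-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xqtlscan import (
    DifferentialTrack,
    QTLSpec,
    ReadthroughScan,
    SkewTrack,
    bonferroni_threshold,
    build_differential,
    calibrate_fdr,
    call_loci,
    moving_window_ttest,
    savitzky_golay_smooth,
    simulate_xqtl_experiment,
)
from xqtlscan.scan import _savgol_dense, count_discoveries


def brute_force_local_regression(y, window, polyorder):
    """Independent oracle: per-point polynomial least squares on the
    (possibly truncated) window, evaluated at the point."""
    n = len(y)
    w = window if window <= n else (n if n % 2 == 1 else n - 1)
    h = w // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        x = np.arange(lo, hi) - i
        deg = min(polyorder, hi - lo - 1)
        out[i] = np.polynomial.polynomial.polyfit(x, y[lo:hi], deg)[0]
    return out


def track(values, markers, **kw):
    return DifferentialTrack(np.asarray(values, dtype=float), markers, **kw)


class TestBuildDifferential:
    def test_identical_arms_zero(self, small_genome, rng):
        v = rng.standard_normal(small_genome.markers.n_markers)
        reps = [SkewTrack(v, small_genome.markers) for _ in range(2)]
        out = build_differential(reps, reps)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_replicate_mean_arithmetic(self, small_genome):
        m = small_genome.markers.n_markers
        wt = [SkewTrack(np.zeros(m), small_genome.markers) for _ in range(2)]
        mut = [
            SkewTrack(np.full(m, 0.2), small_genome.markers),
            SkewTrack(np.full(m, 0.4), small_genome.markers),
        ]
        out = build_differential(wt, mut)
        np.testing.assert_allclose(out.values, 0.3, rtol=1e-12)

    def test_gap_in_any_replicate_propagates(self, small_genome):
        m = small_genome.markers.n_markers
        a = np.zeros(m)
        b = np.zeros(m)
        b[9] = np.nan
        out = build_differential(
            [SkewTrack(a, small_genome.markers)], [SkewTrack(b, small_genome.markers)]
        )
        assert np.isnan(out.values[9])

    def test_empty_arm_rejected(self, small_genome):
        t = SkewTrack(np.zeros(small_genome.markers.n_markers), small_genome.markers)
        with pytest.raises(ValueError):
            build_differential([], [t])

    def test_arm_swap_negates(self, small_genome, rng):
        m = small_genome.markers.n_markers
        wt = [SkewTrack(rng.standard_normal(m), small_genome.markers) for _ in range(2)]
        mut = [SkewTrack(rng.standard_normal(m), small_genome.markers) for _ in range(2)]
        fwd = build_differential(wt, mut)
        rev = build_differential(mut, wt)
        np.testing.assert_allclose(rev.values, -fwd.values, atol=1e-15)


class TestSavitzkyGolay:
    def test_reproduces_cubic_exactly_including_edges(self, small_genome):
        m = small_genome.markers.n_markers
        values = np.empty(m)
        for _, sl in small_genome.markers.iter_chromosomes():
            x = np.linspace(-1, 1, sl.stop - sl.start)
            values[sl] = 0.3 * x**3 - x**2 + 0.5 * x + 2
        out = savitzky_golay_smooth(track(values, small_genome.markers), 31, 3)
        np.testing.assert_allclose(out.values, values, atol=1e-9)

    def test_constant_track_unchanged(self, small_genome):
        values = np.full(small_genome.markers.n_markers, 1.7)
        out = savitzky_golay_smooth(track(values, small_genome.markers), 101, 3)
        np.testing.assert_allclose(out.values, 1.7, rtol=1e-12)

    @pytest.mark.parametrize("window,polyorder", [(5, 2), (11, 3), (31, 3), (101, 3)])
    def test_matches_brute_force_oracle(self, window, polyorder, rng):
        for _ in range(5):
            y = rng.standard_normal(int(rng.integers(window + 2, 300)))
            got = _savgol_dense(y, window, polyorder)
            want = brute_force_local_regression(y, window, polyorder)
            scale = np.max(np.abs(want))
            assert np.max(np.abs(got - want)) <= 1e-10 * max(scale, 1.0)

    def test_window_shrinks_on_short_chromosome(self, rng):
        y = rng.standard_normal(21)  # shorter than the 101 default
        got = _savgol_dense(y, 101, 3)
        want = brute_force_local_regression(y, 21, 3)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_even_window_bumped_to_odd(self, small_genome, rng):
        values = rng.standard_normal(small_genome.markers.n_markers)
        a = savitzky_golay_smooth(track(values, small_genome.markers), 100, 3)
        b = savitzky_golay_smooth(track(values, small_genome.markers), 101, 3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_gaps_skipped_and_preserved(self, small_genome, rng):
        values = rng.standard_normal(small_genome.markers.n_markers)
        values[[10, 200]] = np.nan
        out = savitzky_golay_smooth(track(values, small_genome.markers), 11, 3)
        assert np.isnan(out.values[[10, 200]]).all()
        assert np.isfinite(np.delete(out.values, [10, 200])).all()

    def test_polyorder_must_be_below_window(self, small_genome):
        with pytest.raises(ValueError):
            savitzky_golay_smooth(
                track(np.zeros(small_genome.markers.n_markers), small_genome.markers),
                5,
                5,
            )


def bump_track(markers, centers_values, width=8):
    """Synthetic smoothed-style track with Gaussian bumps at marker indices."""
    v = np.zeros(markers.n_markers)
    idx = np.arange(markers.n_markers)
    for center, height in centers_values:
        v += height * np.exp(-0.5 * ((idx - center) / width) ** 2)
    # zero outside each bump's chromosome is fine: bumps are per-index
    return DifferentialTrack(v, markers, smoothed=True)


class TestCallLoci:
    def test_subthreshold_track_yields_nothing(self, small_genome):
        t = bump_track(small_genome.markers, [(50, 0.1)])
        assert call_loci(t, 0.5) == []

    def test_single_bump_single_call_containing_peak(self, small_genome):
        t = bump_track(small_genome.markers, [(50, 0.6)])
        calls = call_loci(t, 0.3)
        assert len(calls) == 1
        c = calls[0]
        pos = small_genome.markers.positions
        assert c.chrom == "chrI"
        assert c.start_bp <= pos[50] <= c.end_bp
        assert c.peak_pos_bp == pos[50]
        assert c.sign == 1

    def test_two_distant_bumps_two_calls(self, small_genome):
        # chrI index 50 and chrIII index 250: different chromosomes
        t = bump_track(small_genome.markers, [(50, 0.6), (250, -0.6)])
        calls = call_loci(t, 0.3)
        assert len(calls) == 2
        assert {c.sign for c in calls} == {1, -1}

    def test_nearby_same_sign_runs_merge(self, small_genome):
        # Two narrow bumps 7 markers (~35 kb) apart on chrI: the
        # below-threshold stretch is under the 50 kb merge gap.
        t = bump_track(small_genome.markers, [(40, 0.6), (47, 0.6)], width=2)
        calls = call_loci(t, 0.3, merge_gap_bp=50_000)
        assert len(calls) == 1

    def test_opposite_sign_runs_never_merge(self, small_genome):
        t = bump_track(small_genome.markers, [(40, 0.6), (47, -0.6)], width=2)
        calls = call_loci(t, 0.3, merge_gap_bp=50_000)
        assert len(calls) == 2

    def test_edge_exclusion_masks_chromosome_ends(self, small_genome):
        t = bump_track(small_genome.markers, [(0, 0.9), (50, 0.6)], width=2)
        all_calls = call_loci(t, 0.3)
        masked = call_loci(t, 0.3, edge_exclude_probes=10)
        assert len(all_calls) == 2
        assert len(masked) == 1
        assert masked[0].peak_pos_bp == small_genome.markers.positions[50]

    def test_nonpositive_threshold_rejected(self, small_genome):
        t = bump_track(small_genome.markers, [(50, 0.6)])
        with pytest.raises(ValueError):
            call_loci(t, 0.0)


class TestCalibrateFdr:
    def test_zero_control_chooses_smallest_grid_value(self, small_genome):
        control = track(np.zeros(small_genome.markers.n_markers), small_genome.markers)
        grid = np.array([0.1, 0.2, 0.3])
        cal = calibrate_fdr(control, grid=grid)
        assert cal.threshold == pytest.approx(0.1)
        assert cal.achieved
        np.testing.assert_array_equal(cal.false_counts, 0)

    def test_marker_counts_monotone_in_threshold(self, small_genome, rng):
        control = track(
            rng.standard_normal(small_genome.markers.n_markers), small_genome.markers
        )
        counts = [
            count_discoveries(control, t, units="markers")
            for t in np.linspace(0.01, 4, 50)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_no_false_discoveries_above_control_max(self, small_genome, rng):
        control = track(
            0.1 * rng.standard_normal(small_genome.markers.n_markers),
            small_genome.markers,
        )
        top = np.abs(control.values).max()
        assert count_discoveries(control, top * 1.01) == 0

    def test_chosen_threshold_meets_target_estimate(self, small_genome, rng):
        control = track(
            0.1 * rng.standard_normal(small_genome.markers.n_markers),
            small_genome.markers,
        )
        observed = bump_track(small_genome.markers, [(50, 0.8)])
        cal = calibrate_fdr(control, observed=observed)
        i = int(np.flatnonzero(cal.thresholds == cal.threshold)[0])
        assert cal.fdr_estimates[i] <= cal.target_fdr

    def test_unachievable_target_flags_largest(self, small_genome, rng):
        # Control and observed identical: estimated FDR is ~1 until the
        # counts hit zero; with a grid capped below the control max no
        # threshold achieves the target.
        v = 0.1 * rng.standard_normal(small_genome.markers.n_markers)
        control = track(v, small_genome.markers)
        grid = np.linspace(0.001, np.abs(v).max() * 0.5, 20)
        cal = calibrate_fdr(control, observed=control, grid=grid)
        assert not cal.achieved
        assert cal.threshold == pytest.approx(grid[-1])


class TestBonferroni:
    def test_eighteen_thousand_tests(self):
        assert bonferroni_threshold(0.05, 18_000) == pytest.approx(2.78e-6, rel=5e-3)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05


class TestMovingWindowTtest:
    def test_identical_arms_give_p_one(self, small_genome, rng):
        m = small_genome.markers.n_markers
        reps = [SkewTrack(rng.standard_normal(m), small_genome.markers) for _ in range(2)]
        table, loci, _ = moving_window_ttest(reps, reps)
        assert loci == []
        np.testing.assert_allclose(table["p"].dropna(), 1.0, atol=1e-12)

    def test_separated_constant_tracks_hit_zero_p(self, small_genome):
        m = small_genome.markers.n_markers
        wt = [SkewTrack(np.zeros(m), small_genome.markers) for _ in range(2)]
        mut = [SkewTrack(np.full(m, 1.0), small_genome.markers) for _ in range(2)]
        table, loci, _ = moving_window_ttest(wt, mut)
        assert (table["p"] == 0.0).all()
        assert len(loci) >= 1

    def test_requires_two_replicates_per_arm(self, small_genome):
        t = SkewTrack(np.zeros(small_genome.markers.n_markers), small_genome.markers)
        with pytest.raises(ValueError):
            moving_window_ttest([t], [t, t])

    def test_bonferroni_divisor_is_window_count(self, small_genome, rng):
        m = small_genome.markers.n_markers
        wt = [SkewTrack(rng.standard_normal(m), small_genome.markers) for _ in range(2)]
        mut = [SkewTrack(rng.standard_normal(m), small_genome.markers) for _ in range(2)]
        table, _, threshold = moving_window_ttest(wt, mut, window=6)
        n_windows = len(table)
        # 4 chromosomes x (100 - 6 + 1) windows
        assert n_windows == 4 * 95
        assert threshold == pytest.approx(0.05 / n_windows)

    def test_printed_constant_supported_via_config(self, small_genome, rng):
        m = small_genome.markers.n_markers
        wt = [SkewTrack(rng.standard_normal(m), small_genome.markers) for _ in range(2)]
        mut = [SkewTrack(rng.standard_normal(m), small_genome.markers) for _ in range(2)]
        _, _, threshold = moving_window_ttest(wt, mut, n_tests=18_000)
        assert threshold == pytest.approx(0.05 / 18_000)


@pytest.fixture(scope="module")
def strong_scan(medium_genome):
    # Readthrough-dependent QTL (sup35-specific, RM-favoured) at an
    # interior marker of chrXIII; effect difference 0.4, low noise.
    q = 2500
    exp = simulate_xqtl_experiment(
        medium_genome,
        [QTLSpec(q, 0.0, -0.4)],
        n_segregants=4000,
        n_survivors=800,
        noise_sd=0.05,
        n_replicates=2,
        seed=99,
    )
    model = ReadthroughScan.from_experiment(exp)
    return q, model.fit()


class TestScanPipeline:
    """End-to-end behavior on reduced-scale simulated experiments."""

    def test_cross_specific_qtl_called_near_truth(self, medium_genome, strong_scan):
        q, res = strong_scan
        true_chrom = medium_genome.markers.frame["chrom"].iloc[q]
        true_pos = medium_genome.markers.positions[q]
        near = [
            c
            for c in res.loci
            if c.chrom == true_chrom and abs(c.peak_pos_bp - true_pos) <= 50_000
        ]
        assert near, f"no locus within 50 kb of truth; calls: {res.loci}"
        assert near[0].sign == -1  # RM-favoured in the sup35 cross

    def test_strong_locus_found_by_both_methods(self, medium_genome, strong_scan):
        q, res = strong_scan
        true_chrom = medium_genome.markers.frame["chrom"].iloc[q]
        true_pos = medium_genome.markers.positions[q]
        assert res.ttest_loci, "t-test called no loci"
        near = [
            c
            for c in res.ttest_loci
            if c.chrom == true_chrom and abs(c.peak_pos_bp - true_pos) <= 50_000
        ]
        assert near, "Bonferroni t-test missed the strong planted locus"

    def test_shared_qtl_cancels_in_differential(self, medium_genome):
        # Equal effects in both crosses: skews present per cross but the
        # differential stays null and no locus survives calibration.
        q = 1500
        exp = simulate_xqtl_experiment(
            medium_genome,
            [QTLSpec(q, 0.4, 0.4)],
            n_segregants=3000,
            n_survivors=600,
            noise_sd=0.05,
            n_replicates=2,
            seed=123,
        )
        res = ReadthroughScan.from_experiment(exp).fit(run_ttest=False)
        true_chrom = medium_genome.markers.frame["chrom"].iloc[q]
        true_pos = medium_genome.markers.positions[q]
        near = [
            c
            for c in res.loci
            if c.chrom == true_chrom and abs(c.peak_pos_bp - true_pos) <= 50_000
        ]
        assert not near, f"shared QTL wrongly called readthrough-dependent: {near}"

    def test_summary_mentions_locus_count(self, strong_scan):
        _, res = strong_scan
        text = res.summary()
        assert "loci called (SG/FDR)" in text
        assert str(len(res.loci)) in text

    def test_plot_draws_all_chromosomes(self, strong_scan):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, res = strong_scan
        ax = res.plot()
        assert len(ax.lines) >= 16  # one trace per chromosome
        plt.close("all")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), window=st.sampled_from([5, 11, 21]))
def test_sg_oracle_equivalence_property(seed, window):
    """SG smoother equals local polynomial regression on arbitrary inputs."""
    r = np.random.default_rng(seed)
    y = r.standard_normal(int(r.integers(window + 2, 150)))
    got = _savgol_dense(y, window, 3)
    want = brute_force_local_regression(y, window, 3)
    assert np.max(np.abs(got - want)) <= 1e-10 * max(np.max(np.abs(want)), 1.0)
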