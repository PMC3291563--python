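"""Detection of readthrough-dependent loci from paired-cross skew tracks.

The input is background-subtracted allele-frequency skew tracks for the
two crosses (wildtype and sup35), two or more biological replicates
each.  The differential track — mean(sup35 replicates) minus
mean(wildtype replicates) — is smoothed with a Savitzky-Golay filter
(local polynomial regression in 101-probe windows) and thresholded at a
5% empirical FDR, where false discoveries per candidate threshold are
counted by running the identical algorithm on a null differential built
from the matched rich-medium (YPD) experiment.  A moving 6-probe
Welch t-test with Bonferroni correction provides an independent
confirmation scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_coeffs

from .arrays import SkewTrack
from .genome import MarkerMap

logger = logging.getLogger(__name__)

DEFAULT_SG_WINDOW = 101  # nearest odd size to the 100-probe smoothing window
DEFAULT_SG_POLYORDER = 3
DEFAULT_MERGE_GAP_BP = 50_000


@dataclass
class DifferentialTrack:
    """Per-marker difference of replicate-mean skews between the crosses.

    Positive values: the sup35 cross is more BY-enriched than the
    wildtype cross at that marker.  Defined (finite) only on markers
    present in all contributing replicate tracks.
    """

    values: np.ndarray
    markers: MarkerMap
    n_wildtype: int = 0
    n_mutant: int = 0
    smoothed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.markers.n_markers,):
            raise ValueError("values length must equal marker count")

    def __len__(self):
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = self.markers.frame[["chrom", "pos_bp", "marker_id"]].copy()
        df["value"] = self.values
        return df


@dataclass(frozen=True)
class LocusCall:
    """A called readthrough-dependent region."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_marker_id: str
    peak_pos_bp: int
    peak_value: float
    sign: int  # +1 BY-direction, -1 RM-direction
    method: str  # "sg_fdr" or "ttest_bonferroni"
    n_markers: int = 0

    def __post_init__(self):
        if not self.start_bp <= self.peak_pos_bp <= self.end_bp:
            raise ValueError("peak must lie inside the locus interval")


@dataclass
class FdrCalibration:
    """Empirical-FDR calibration table for locus calling.

    For every candidate threshold, ``false_counts`` holds the number of
    (false) discoveries the calling algorithm makes on the null
    (control) differential and ``real_counts`` the discoveries on the
    observed differential; ``threshold`` is the smallest grid value with
    estimated FDR ``false / max(1, real) <= target_fdr``.
    """

    thresholds: np.ndarray
    false_counts: np.ndarray
    real_counts: np.ndarray
    target_fdr: float
    threshold: float
    achieved: bool = True

    @property
    def fdr_estimates(self) -> np.ndarray:
        return self.false_counts / np.maximum(self.real_counts, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "false_discoveries": self.false_counts,
                "real_discoveries": self.real_counts,
                "fdr_estimate": self.fdr_estimates,
            }
        )


def build_differential(
    wt_reps: list[SkewTrack], mut_reps: list[SkewTrack]
) -> DifferentialTrack:
    """mean(sup35 replicate skews) - mean(wildtype replicate skews).

    All replicates must share one marker map.  A marker missing (NaN) in
    any replicate is a gap in the differential.
    """
    if not wt_reps or not mut_reps:
        raise ValueError("need at least one replicate per arm")
    markers = wt_reps[0].markers
    for t in (*wt_reps, *mut_reps):
        if not t.markers.same_map(markers):
            raise ValueError("replicate tracks have different marker maps")
    wt = np.mean([t.values for t in wt_reps], axis=0)
    mut = np.mean([t.values for t in mut_reps], axis=0)
    return DifferentialTrack(
        mut - wt, markers, n_wildtype=len(wt_reps), n_mutant=len(mut_reps)
    )


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing
# ---------------------------------------------------------------------------

def _polyfit_eval_at_zero(x: np.ndarray, y: np.ndarray, polyorder: int) -> float:
    """Least-squares polynomial fit evaluated at x = 0 (the target point)."""
    deg = min(polyorder, len(x) - 1)
    return float(np.polynomial.polynomial.polyfit(x, y, deg)[0])


def _savgol_dense(y: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """SG-smooth a gap-free 1-D series in probe-index units.

    Interior points use the standard SG convolution weights (the exact
    least-squares solution for a centred window); points within half a
    window of either end are fitted on the truncated one-sided window —
    a genuine boundary least-squares fit, not mirroring — so the whole
    output equals brute-force local polynomial regression.
    """
    n = len(y)
    if n == 0:
        return y.copy()
    w = window if window <= n else (n if n % 2 == 1 else n - 1)
    if w != window:
        logger.warning("shrinking SG window from %d to %d (short chromosome)", window, w)
    order = min(polyorder, w - 1)
    half = w // 2
    out = np.empty(n)
    coefs = savgol_coeffs(w, order)
    out[half : n - half] = np.convolve(y, coefs, mode="valid")
    for i in range(half):
        # left edge: point i, window [0, i + half], offsets -i .. +half
        x = np.arange(0, i + half + 1) - i
        out[i] = _polyfit_eval_at_zero(x, y[: i + half + 1], order)
        # right edge: point n-1-i, window [n-1-i-half, n-1], offsets -half .. +i
        x = np.arange(-half, i + 1)
        out[n - 1 - i] = _polyfit_eval_at_zero(x, y[n - 1 - i - half :], order)
    return out


def savitzky_golay_smooth(
    track: DifferentialTrack,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
) -> DifferentialTrack:
    """Local polynomial regression in ``window``-probe sliding windows.

    Smoothing runs per chromosome in probe-index units, never crossing a
    chromosome boundary; gaps are skipped (the window always holds
    ``window`` informative probes) and stay NaN in the output.  An even
    ``window`` is bumped to the next odd size; a chromosome shorter than
    the window shrinks it to the largest valid odd size.
    """
    if window % 2 == 0:
        window += 1
        logger.info("SG window must be odd; using %d", window)
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    out = np.full_like(track.values, np.nan)
    for _, sl in track.markers.iter_chromosomes():
        v = track.values[sl]
        finite = np.isfinite(v)
        if not finite.any():
            continue
        smoothed = _savgol_dense(v[finite], window, polyorder)
        block = np.full(len(v), np.nan)
        block[finite] = smoothed
        out[sl] = block
    return replace(track, values=out, smoothed=True)


# ---------------------------------------------------------------------------
# Locus calling and empirical FDR
# ---------------------------------------------------------------------------

def call_loci(
    smoothed: DifferentialTrack,
    threshold: float,
    merge_gap_bp: float = DEFAULT_MERGE_GAP_BP,
    method: str = "sg_fdr",
    edge_exclude_probes: int = 0,
) -> list[LocusCall]:
    """Contiguous same-sign runs with ``|value| >= threshold``.

    Runs on one chromosome with the same sign separated by less than
    ``merge_gap_bp`` are merged; each call's peak is its marker of
    maximal ``|value|`` (ties broken leftmost).

    ``edge_exclude_probes`` masks that many markers at each chromosome
    end from thresholding.  Within half a smoothing window of an end the
    local polynomial fit is one-sided (extrapolative) and its variance
    is several-fold the interior variance; excluding the margin keeps
    the empirical-FDR threshold governed by interior noise.  The scan
    model applies this with half its smoothing window by default.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    calls: list[LocusCall] = []
    mf = smoothed.markers.frame
    for chrom, sl in smoothed.markers.iter_chromosomes():
        v = smoothed.values[sl]
        pos = smoothed.markers.positions[sl]
        with np.errstate(invalid="ignore"):
            above = np.abs(v) >= threshold
        above &= np.isfinite(v)
        if edge_exclude_probes > 0:
            above[:edge_exclude_probes] = False
            if edge_exclude_probes < len(above):
                above[-edge_exclude_probes:] = False
            else:
                above[:] = False
        if not above.any():
            continue
        sign = np.sign(v)
        runs: list[list[int]] = []  # list of marker-index lists (chrom-local)
        idx = np.flatnonzero(above)
        cur = [idx[0]]
        for j in idx[1:]:
            prev = cur[-1]
            same_sign = sign[j] == sign[prev]
            contiguous = j == prev + 1
            near = (pos[j] - pos[prev]) < merge_gap_bp
            if same_sign and (contiguous or near):
                cur.append(j)
            else:
                runs.append(cur)
                cur = [j]
        runs.append(cur)
        for run in runs:
            run = np.asarray(run)
            vals = v[run]
            peak_local = run[int(np.argmax(np.abs(vals)))]
            gi = sl.start + peak_local
            calls.append(
                LocusCall(
                    chrom=chrom,
                    start_bp=int(pos[run[0]]),
                    end_bp=int(pos[run[-1]]),
                    peak_marker_id=str(mf["marker_id"].iloc[gi]),
                    peak_pos_bp=int(pos[peak_local]),
                    peak_value=float(v[peak_local]),
                    sign=int(np.sign(v[peak_local])),
                    method=method,
                    n_markers=len(run),
                )
            )
    return calls


def count_discoveries(
    smoothed: DifferentialTrack,
    threshold: float,
    merge_gap_bp: float = DEFAULT_MERGE_GAP_BP,
    units: str = "loci",
    edge_exclude_probes: int = 0,
) -> int:
    """Number of discoveries at a threshold, counted as loci or markers."""
    if units == "loci":
        return len(
            call_loci(
                smoothed,
                threshold,
                merge_gap_bp,
                edge_exclude_probes=edge_exclude_probes,
            )
        )
    if units == "markers":
        values = smoothed.values
        if edge_exclude_probes > 0:
            values = values.copy()
            for _, sl in smoothed.markers.iter_chromosomes():
                values[sl.start : sl.start + edge_exclude_probes] = np.nan
                values[max(sl.stop - edge_exclude_probes, sl.start) : sl.stop] = np.nan
        with np.errstate(invalid="ignore"):
            return int(np.nansum(np.abs(values) >= threshold))
    raise ValueError("units must be 'loci' or 'markers'")


def calibrate_fdr(
    control: DifferentialTrack,
    observed: DifferentialTrack | None = None,
    grid: np.ndarray | None = None,
    target_fdr: float = 0.05,
    merge_gap_bp: float = DEFAULT_MERGE_GAP_BP,
    units: str = "loci",
    grid_size: int = 200,
    edge_exclude_probes: int = 0,
) -> FdrCalibration:
    """Choose the locus-calling threshold at a target empirical FDR.

    ``control`` must be a null differential smoothed identically to the
    observed one (here: the rich-medium experiment's sup35-minus-wildtype
    differential).  For each candidate threshold the calling algorithm
    runs on the control track to count false discoveries; the chosen
    threshold is the smallest grid value whose estimated FDR
    ``false / max(1, observed discoveries)`` is at or below
    ``target_fdr``.  Without an observed track the criterion reduces to
    zero false discoveries.  If no grid value meets the target the
    largest is returned with ``achieved=False``.
    """
    eligible = control.values
    if edge_exclude_probes > 0:
        eligible = eligible.copy()
        for _, sl in control.markers.iter_chromosomes():
            eligible[sl.start : sl.start + edge_exclude_probes] = np.nan
            eligible[max(sl.stop - edge_exclude_probes, sl.start) : sl.stop] = np.nan
    finite = eligible[np.isfinite(eligible)]
    if finite.size == 0:
        raise ValueError("control differential has no finite values")
    if grid is None:
        top = float(np.abs(finite).max()) * 1.1
        if top <= 0:
            top = 1e-12
        grid = np.linspace(0.0, top, grid_size)
    grid = np.asarray(grid, dtype=float)
    # threshold 0 is not callable; replace it with the smallest positive step
    positive = grid[grid > 0]
    if positive.size == 0:
        raise ValueError("grid must contain positive thresholds")
    false_counts = np.array(
        [
            count_discoveries(control, t, merge_gap_bp, units, edge_exclude_probes)
            for t in positive
        ]
    )
    if observed is not None:
        real_counts = np.array(
            [
                count_discoveries(observed, t, merge_gap_bp, units, edge_exclude_probes)
                for t in positive
            ]
        )
    else:
        real_counts = np.zeros_like(false_counts)
    fdr = false_counts / np.maximum(real_counts, 1)
    ok = np.flatnonzero(fdr <= target_fdr)
    if ok.size:
        chosen, achieved = float(positive[ok[0]]), True
    else:
        chosen, achieved = float(positive[-1]), False
        logger.warning(
            "no grid threshold achieves FDR <= %g; returning largest (%g)",
            target_fdr,
            chosen,
        )
    return FdrCalibration(
        thresholds=positive,
        false_counts=false_counts,
        real_counts=real_counts,
        target_fdr=target_fdr,
        threshold=chosen,
        achieved=achieved,
    )


# ---------------------------------------------------------------------------
# Moving-window t-test
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 18_000) -> float:
    """Bonferroni-corrected per-test p-value threshold: alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def moving_window_ttest(
    wt_reps: list[SkewTrack],
    mut_reps: list[SkewTrack],
    window: int = 6,
    alpha: float = 0.05,
    n_tests: int | None = None,
    merge_gap_bp: float = DEFAULT_MERGE_GAP_BP,
) -> tuple[pd.DataFrame, list[LocusCall], float]:
    """Welch t-test of pooled skews in a moving window of consecutive probes.

    For every window of ``window`` consecutive same-chromosome markers
    the background-subtracted values of all wildtype replicates
    (replicates x window values) are compared against the sup35
    replicates.  Windows below the Bonferroni-corrected threshold
    (``alpha`` divided by ``n_tests``, default the number of windows
    actually tested) are merged into loci.

    Returns ``(window table, loci, p-value threshold)``.
    """
    if len(wt_reps) < 2 or len(mut_reps) < 2:
        raise ValueError("need >= 2 replicates per arm for the t-test")
    markers = wt_reps[0].markers
    for t in (*wt_reps, *mut_reps):
        if not t.markers.same_map(markers):
            raise ValueError("replicate tracks have different marker maps")
    wt = np.vstack([t.values for t in wt_reps])
    mut = np.vstack([t.values for t in mut_reps])
    rows = []
    for chrom, sl in markers.iter_chromosomes():
        nw = sl.stop - sl.start - window + 1
        if nw < 1:
            continue
        wview = np.lib.stride_tricks.sliding_window_view(wt[:, sl], window, axis=1)
        mview = np.lib.stride_tricks.sliding_window_view(mut[:, sl], window, axis=1)
        # (reps, windows, window) -> (windows, reps * window)
        a = np.moveaxis(wview, 0, 1).reshape(nw, -1)
        b = np.moveaxis(mview, 0, 1).reshape(nw, -1)
        valid = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
        pvals = np.full(nw, np.nan)
        if valid.any():
            import warnings

            with warnings.catch_warnings():
                # near-constant windows trip scipy's precision warning;
                # the degenerate cases are resolved explicitly below
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(a[valid], b[valid], axis=1, equal_var=False)
            p = np.asarray(res.pvalue)
            # Degenerate windows: zero variance in both groups gives NaN;
            # report p=0 for separated means, p=1 for equal means.
            va = a[valid].var(axis=1)
            vb = b[valid].var(axis=1)
            degen = (va == 0) & (vb == 0)
            if degen.any():
                means_differ = a[valid].mean(axis=1) != b[valid].mean(axis=1)
                p = np.where(degen, np.where(means_differ, 0.0, 1.0), p)
                logger.warning(
                    "%d zero-variance windows handled by convention", int(degen.sum())
                )
            pvals[valid] = p
        pos = markers.positions[sl]
        for i in range(nw):
            rows.append(
                (
                    chrom,
                    int(pos[i]),
                    int(pos[i + window - 1]),
                    sl.start + i,
                    pvals[i],
                )
            )
    table = pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "first_marker_index", "p"]
    )
    n_valid = int(table["p"].notna().sum())
    divisor = n_tests if n_tests is not None else max(n_valid, 1)
    threshold = bonferroni_threshold(alpha, divisor)
    table["significant"] = table["p"] < threshold

    # Merge significant windows into loci using a -log10(p) marker score.
    score = np.full(markers.n_markers, np.nan)
    sig = table[table["significant"]]
    for _, row in sig.iterrows():
        i0 = int(row["first_marker_index"])
        for j in range(i0, i0 + window):
            s = -np.log10(max(row["p"], 1e-300))
            if not np.isfinite(score[j]) or s > score[j]:
                score[j] = s
    score_track = DifferentialTrack(score, markers, smoothed=True)
    cutoff = -np.log10(threshold)
    loci = (
        call_loci(score_track, cutoff, merge_gap_bp, method="ttest_bonferroni")
        if np.isfinite(score).any()
        else []
    )
    return table, loci, threshold


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ReadthroughScan:
    """Differential X-QTL scan model for one growth condition.

    Parameters
    ----------
    wt_selection, mut_selection : list of SkewTrack
        Background-subtracted (selection minus control) replicate tracks
        for the wildtype and sup35 crosses under the condition.
    null_wt, null_mut : list of SkewTrack
        The same for the matched rich-medium (YPD) experiment; their
        differential is the empirical null used to calibrate the FDR
        threshold.
    window, polyorder : int
        Savitzky-Golay smoothing window (probes) and polynomial order.
    """

    def __init__(
        self,
        wt_selection: list[SkewTrack],
        mut_selection: list[SkewTrack],
        null_wt: list[SkewTrack],
        null_mut: list[SkewTrack],
        window: int = DEFAULT_SG_WINDOW,
        polyorder: int = DEFAULT_SG_POLYORDER,
        merge_gap_bp: float = DEFAULT_MERGE_GAP_BP,
    ):
        self.wt_selection = list(wt_selection)
        self.mut_selection = list(mut_selection)
        self.null_wt = list(null_wt)
        self.null_mut = list(null_mut)
        self.window = window
        self.polyorder = polyorder
        self.merge_gap_bp = merge_gap_bp

    @classmethod
    def from_experiment(cls, experiment, normalize: bool = True, **kwargs):
        """Build the model straight from simulated raw intensity tables."""
        from .arrays import background_subtract, skew_track_from_raw

        def subtracted(cross, sel_arm, ctl_arm):
            out = []
            for rep in range(1, experiment.n_replicates + 1):
                sel = skew_track_from_raw(
                    experiment.tables[(cross, sel_arm, rep)],
                    experiment.markers,
                    normalize=normalize,
                    cross=cross,
                    arm=sel_arm,
                    replicate=rep,
                )
                ctl = skew_track_from_raw(
                    experiment.tables[(cross, ctl_arm, rep)],
                    experiment.markers,
                    normalize=normalize,
                    cross=cross,
                    arm=ctl_arm,
                    replicate=rep,
                )
                out.append(background_subtract(sel, ctl))
            return out

        return cls(
            wt_selection=subtracted("wildtype", "selection", "control"),
            mut_selection=subtracted("sup35", "selection", "control"),
            null_wt=subtracted("wildtype", "ypd_selection", "ypd_control"),
            null_mut=subtracted("sup35", "ypd_selection", "ypd_control"),
            **kwargs,
        )

    def fit(
        self,
        target_fdr: float = 0.05,
        run_ttest: bool = True,
        ttest_window: int = 6,
        ttest_alpha: float = 0.05,
        ttest_n_tests: int | None = None,
        fdr_units: str = "loci",
    ) -> "ScanResults":
        differential = build_differential(self.wt_selection, self.mut_selection)
        smoothed = savitzky_golay_smooth(differential, self.window, self.polyorder)
        null_diff = build_differential(self.null_wt, self.null_mut)
        null_smoothed = savitzky_golay_smooth(null_diff, self.window, self.polyorder)
        edge = self.window // 2
        calibration = calibrate_fdr(
            null_smoothed,
            observed=smoothed,
            target_fdr=target_fdr,
            merge_gap_bp=self.merge_gap_bp,
            units=fdr_units,
            edge_exclude_probes=edge,
        )
        loci = call_loci(
            smoothed,
            calibration.threshold,
            self.merge_gap_bp,
            edge_exclude_probes=edge,
        )
        ttest_table = ttest_loci = ttest_threshold = None
        if run_ttest:
            ttest_table, ttest_loci, ttest_threshold = moving_window_ttest(
                self.wt_selection,
                self.mut_selection,
                window=ttest_window,
                alpha=ttest_alpha,
                n_tests=ttest_n_tests,
                merge_gap_bp=self.merge_gap_bp,
            )
        return ScanResults(
            model=self,
            differential=differential,
            smoothed=smoothed,
            null_smoothed=null_smoothed,
            calibration=calibration,
            loci=loci,
            ttest_table=ttest_table,
            ttest_loci=ttest_loci,
            ttest_threshold=ttest_threshold,
        )


@dataclass
class ScanResults:
    """Fitted scan: smoothed tracks, calibrated threshold and locus calls."""

    model: ReadthroughScan
    differential: DifferentialTrack
    smoothed: DifferentialTrack
    null_smoothed: DifferentialTrack
    calibration: FdrCalibration
    loci: list[LocusCall]
    ttest_table: pd.DataFrame | None = None
    ttest_loci: list[LocusCall] | None = None
    ttest_threshold: float | None = None

    @property
    def threshold(self) -> float:
        return self.calibration.threshold

    def loci_frame(self) -> pd.DataFrame:
        return loci_to_frame(self.loci)

    def summary(self) -> str:
        lines = [
            "Readthrough-dependent locus scan",
            "=" * 34,
            f"markers: {self.differential.markers.n_markers}"
            f"  wildtype reps: {self.differential.n_wildtype}"
            f"  sup35 reps: {self.differential.n_mutant}",
            f"SG window: {self.model.window} probes, order {self.model.polyorder}",
            f"empirical FDR target: {self.calibration.target_fdr:g}"
            f"  threshold: {self.threshold:.4g}"
            f"  (achieved: {self.calibration.achieved})",
            f"loci called (SG/FDR): {len(self.loci)}",
        ]
        if self.ttest_loci is not None:
            lines.append(
                f"loci called (6-probe t-test, p < {self.ttest_threshold:.3g}): "
                f"{len(self.ttest_loci)}"
            )
        if self.loci:
            lines.append("")
            lines.append(self.loci_frame().to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Genome-wide smoothed differential with called loci shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 3))
        offset = 0
        ticks, labels = [], []
        for chrom, sl in self.smoothed.markers.iter_chromosomes():
            pos = self.smoothed.markers.positions[sl] + offset
            ax.plot(pos, self.smoothed.values[sl], lw=0.8, color="#33557a")
            ticks.append(pos.mean())
            labels.append(chrom.replace("chr", ""))
            for locus in self.loci:
                if locus.chrom == chrom:
                    ax.axvspan(
                        locus.start_bp + offset,
                        locus.end_bp + offset,
                        color="#d95f02",
                        alpha=0.3,
                    )
            offset = pos[-1]
        ax.axhline(self.threshold, ls="--", lw=0.8, color="grey")
        ax.axhline(-self.threshold, ls="--", lw=0.8, color="grey")
        ax.axhline(0, lw=0.5, color="black")
        ax.set_xticks(ticks, labels)
        ax.set_ylabel("smoothed $\\Delta$ skew (sup35 $-$ WT)")
        ax.set_xlabel("chromosome")
        return ax


def loci_to_frame(loci: list[LocusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start_bp": c.start_bp,
                "end_bp": c.end_bp,
                "peak_marker_id": c.peak_marker_id,
                "peak_pos_bp": c.peak_pos_bp,
                "peak_value": c.peak_value,
                "sign": c.sign,
                "method": c.method,
                "n_markers": c.n_markers,
            }
            for c in loci
        ],
        columns=[
            "chrom",
            "start_bp",
            "end_bp",
            "peak_marker_id",
            "peak_pos_bp",
            "peak_value",
            "sign",
            "method",
            "n_markers",
        ],
    )
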