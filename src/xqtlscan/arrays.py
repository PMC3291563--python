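"""From raw two-channel probe intensities to allele-frequency skew tracks.

A skew track holds, per marker, the difference of log10 sample/reference
ratios of the BY- and RM-specific probes: positive values mean the pool
is enriched for the BY allele, negative for RM.  Ratios to the common
BY/RM-diploid reference cancel probe-affinity effects.  Missing probes
become NaN gaps that propagate through arithmetic and are excluded from
window means (never imputed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome import MarkerMap

logger = logging.getLogger(__name__)

INTENSITY_COLUMNS = ["marker_id", "sample_BY", "sample_RM", "ref_BY", "ref_RM"]
_CHANNELS = ["sample_BY", "sample_RM", "ref_BY", "ref_RM"]


@dataclass
class SkewTrack:
    """Marker-aligned allele-frequency skew values for one pool.

    ``values`` is a float vector aligned to ``markers`` (NaN = gap).
    ``cross``/``arm``/``replicate`` label the pool the array came from.
    """

    values: np.ndarray
    markers: MarkerMap
    cross: str = ""
    arm: str = ""
    replicate: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.markers.n_markers,):
            raise ValueError("values length must equal marker count")

    def __len__(self):
        return len(self.values)

    @property
    def gaps(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = self.markers.frame[["chrom", "pos_bp", "marker_id"]].copy()
        df["skew"] = self.values
        return df


def normalize_intensities(
    raw: pd.DataFrame,
    rank_tolerance: float = 0.02,
    rank_trim: float = 0.025,
    min_subset: int = 20,
) -> pd.DataFrame:
    """Rank-invariant scaling of the sample channel onto the reference.

    All probes of the array (BY- and RM-specific alike) are pooled; the
    rank-invariant subset is the probes whose intensity rank differs
    between the sample and reference channels by less than
    ``rank_tolerance`` (a fraction of the probe count), excluding the
    ``rank_trim`` tails.  A single multiplicative factor — the geometric
    mean of reference/sample over that subset — is fitted and applied to
    the sample channel, so a pure dye bias is removed exactly.  Row
    order is preserved.

    Non-positive intensities are floored to the smallest positive
    observed intensity (logged); more than 50% non-positive raises.
    """
    df = raw.copy()
    vals = df[_CHANNELS].to_numpy(dtype=float)
    nonpos = ~(vals > 0)
    if nonpos.any():
        if nonpos.mean() > 0.5:
            raise ValueError(
                f"{nonpos.mean():.0%} of intensities non-positive; refusing to normalize"
            )
        floor = vals[vals > 0].min()
        vals = np.where(nonpos, floor, vals)
        logger.warning(
            "floored %d non-positive intensities to %g", int(nonpos.sum()), floor
        )
        df[_CHANNELS] = vals

    sample = np.concatenate([vals[:, 0], vals[:, 1]])
    ref = np.concatenate([vals[:, 2], vals[:, 3]])
    n = len(sample)
    rs, rr = rankdata(sample), rankdata(ref)
    subset = np.abs(rs - rr) <= rank_tolerance * n
    subset &= (rr > rank_trim * n) & (rr <= (1.0 - rank_trim) * n)
    if subset.sum() < min_subset:
        # Degenerate reference (e.g. constant channel): fall back to the
        # trimmed full probe set for the scale fit.
        logger.warning(
            "rank-invariant subset too small (%d); using all probes", int(subset.sum())
        )
        subset = np.ones(n, dtype=bool)
    scale = 10.0 ** np.mean(np.log10(ref[subset]) - np.log10(sample[subset]))
    df["sample_BY"] = df["sample_BY"].to_numpy(dtype=float) * scale
    df["sample_RM"] = df["sample_RM"].to_numpy(dtype=float) * scale
    df.attrs["normalization_scale"] = float(scale)
    df.attrs["rank_invariant_n"] = int(subset.sum())
    return df


def compute_skew(
    normalized: pd.DataFrame, markers: MarkerMap, **labels
) -> SkewTrack:
    """log10(sample_BY/ref_BY) - log10(sample_RM/ref_RM) per marker.

    Markers absent from the table, or with any non-finite/non-positive
    probe intensity, become NaN gaps (flagged, not zeroed).
    """
    idx = normalized.set_index("marker_id")
    values = np.full(markers.n_markers, np.nan)
    present = markers.marker_ids.isin(idx.index)
    sub = idx.reindex(markers.marker_ids[present])
    with np.errstate(divide="ignore", invalid="ignore"):
        sby, srm = sub["sample_BY"].to_numpy(), sub["sample_RM"].to_numpy()
        rby, rrm = sub["ref_BY"].to_numpy(), sub["ref_RM"].to_numpy()
        skew = np.log10(sby / rby) - np.log10(srm / rrm)
    skew[~np.isfinite(skew)] = np.nan
    values[np.flatnonzero(present)] = skew
    n_gaps = int(np.isnan(values).sum())
    if n_gaps:
        logger.info("compute_skew: %d markers flagged as gaps", n_gaps)
    return SkewTrack(values, markers, **labels)


def background_subtract(selection: SkewTrack, control: SkewTrack) -> SkewTrack:
    """Remove pool-construction skew: selection minus control, per marker.

    Both tracks must share the marker map; gaps propagate.
    """
    if not selection.markers.same_map(control.markers):
        raise ValueError("selection and control tracks have different marker maps")
    out = replace(
        selection,
        values=selection.values - control.values,
        arm=f"{selection.arm}-minus-{control.arm}" if selection.arm else "subtracted",
    )
    return out


def sliding_window_average(track: SkewTrack, window_bp: float = 40_000) -> SkewTrack:
    """Mean skew of markers within +/- window_bp/2, per marker.

    Windows are closed intervals centred on each marker, never cross a
    chromosome boundary, and exclude NaN gaps from the mean.  A marker
    whose window holds no finite value stays NaN.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    half = window_bp / 2.0
    out = np.full_like(track.values, np.nan)
    for _, sl in track.markers.iter_chromosomes():
        pos = track.markers.positions[sl].astype(float)
        v = track.values[sl]
        finite = np.isfinite(v)
        cs = np.concatenate([[0.0], np.cumsum(np.where(finite, v, 0.0))])
        cn = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        total = cs[hi] - cs[lo]
        count = cn[hi] - cn[lo]
        with np.errstate(invalid="ignore"):
            out[sl] = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return replace(track, values=out, meta={**track.meta, "window_bp": window_bp})


def skew_track_from_raw(
    raw: pd.DataFrame, markers: MarkerMap, normalize: bool = True, **labels
) -> SkewTrack:
    """Convenience: normalize a raw intensity table and compute its skew."""
    table = normalize_intensities(raw) if normalize else raw
    return compute_skew(table, markers, **labels)
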