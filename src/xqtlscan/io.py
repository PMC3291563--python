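"""Plain-text readers and writers for the pipeline's tables.

Formats: marker map and intensity tables as TSV, growth curves as a wide
plate-reader CSV (time column + one column per well) with a well-map
TSV, luciferase readings as CSV, locus calls as BED + full-field TSV,
windowed tracks as bedGraph-like TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arrays import INTENSITY_COLUMNS, SkewTrack
from .genome import MARKER_MAP_COLUMNS, MarkerMap
from .growth import GrowthCurve
from .luciferase import LUCIFERASE_COLUMNS
from .scan import LocusCall, loci_to_frame


def write_marker_map(markers: MarkerMap, path) -> None:
    markers.frame[MARKER_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def write_intensities(table: pd.DataFrame, path) -> None:
    table[INTENSITY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_intensities(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_skew_track(track: SkewTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)


def read_skew_track(path, markers: MarkerMap, **labels) -> SkewTrack:
    df = pd.read_csv(path, sep="\t")
    aligned = df.set_index("marker_id").reindex(markers.marker_ids)
    return SkewTrack(aligned["skew"].to_numpy(dtype=float), markers, **labels)


def write_bedgraph(track: SkewTrack, path) -> None:
    """Half-open 0-based intervals around each marker (browser-friendly)."""
    df = track.markers.frame[["chrom", "pos_bp"]].copy()
    df["start"] = df["pos_bp"] - 1
    df["end"] = df["pos_bp"]
    df["value"] = track.values
    df[["chrom", "start", "end", "value"]].dropna().to_csv(
        path, sep="\t", index=False, header=False
    )


def write_loci_bed(loci: list[LocusCall], path, score_scale: float = 1000.0) -> None:
    """BED6: score = peak |value| scaled/capped, strand encodes skew sign."""
    rows = []
    for i, c in enumerate(loci):
        score = int(min(abs(c.peak_value) * score_scale, 1000))
        rows.append(
            (
                c.chrom,
                c.start_bp - 1,
                c.end_bp,
                f"locus_{i + 1}_{c.method}",
                score,
                "+" if c.sign >= 0 else "-",
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_loci_table(loci: list[LocusCall], path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def write_plate_csv(curves: list[GrowthCurve], path) -> None:
    """Wide CSV: a ``time_h`` column plus one OD column per well."""
    if not curves:
        raise ValueError("no curves to write")
    t = curves[0].time_h
    data = {"time_h": t}
    for c in curves:
        if not np.array_equal(c.time_h, t):
            raise ValueError("all curves must share the time grid for wide CSV")
        data[c.well or f"well{len(data)}"] = c.od
    pd.DataFrame(data).to_csv(path, index=False)


def write_well_map(curves: list[GrowthCurve], path) -> None:
    pd.DataFrame(
        [
            {
                "well": c.well,
                "strain": c.strain,
                "genotype": c.genotype,
                "condition": c.condition,
                "replicate": c.replicate,
            }
            for c in curves
        ]
    ).to_csv(path, sep="\t", index=False)


def read_plate_csv(path, well_map_path=None) -> list[GrowthCurve]:
    """Read a wide plate CSV (and optional well-map TSV) into curves."""
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError("plate CSV needs a 'time_h' column")
    labels = {}
    if well_map_path is not None:
        wm = pd.read_csv(well_map_path, sep="\t").set_index("well")
        labels = wm.to_dict("index")
    t = df["time_h"].to_numpy(dtype=float)
    curves = []
    for well in df.columns:
        if well == "time_h":
            continue
        meta = labels.get(well, {})
        curves.append(
            GrowthCurve(
                time_h=t,
                od=df[well].to_numpy(dtype=float),
                well=str(well),
                strain=str(meta.get("strain", "")),
                genotype=str(meta.get("genotype", "")),
                condition=str(meta.get("condition", "")),
                replicate=int(meta.get("replicate", 0) or 0),
            )
        )
    return curves


def write_luciferase_csv(readings: pd.DataFrame, path) -> None:
    readings[LUCIFERASE_COLUMNS].to_csv(path, index=False)


def read_luciferase_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
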