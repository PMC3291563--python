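"""Percent stop-codon readthrough from dual-luciferase readings.

The reporter is a tandem Renilla-firefly construct separated by either a
stop codon (readthrough reporter) or a sense codon (100% reference).
Per replicate the blank-subtracted firefly/Renilla ratio is formed for
each construct; percent readthrough is 100 x mean(stop ratios) /
mean(sense ratios).  Replicate ratios are averaged (mean-of-ratios)
because per-assay values exist and carry the reported dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import MIN_MEASUREMENTS

logger = logging.getLogger(__name__)

LUCIFERASE_COLUMNS = ["construct", "firefly", "renilla", "strain", "replicate", "is_blank"]


@dataclass
class ReadthroughEstimate:
    """Percent readthrough with its across-replicate dispersion."""

    percent: float
    sd: float
    n_measurements: int
    n_dropped: int = 0
    flag: str = ""

    @property
    def fraction(self) -> float:
        return self.percent / 100.0


def _ratios(df: pd.DataFrame, f_blank: float, r_blank: float) -> tuple[np.ndarray, int]:
    firefly = df["firefly"].to_numpy(dtype=float) - f_blank
    renilla = df["renilla"].to_numpy(dtype=float) - r_blank
    good = renilla > 0
    dropped = int((~good).sum())
    if dropped:
        logger.warning("dropped %d readings with non-positive Renilla signal", dropped)
    # Firefly can legitimately hit zero signal above blank (no readthrough);
    # clamp at 0 so the estimate stays non-negative.
    return np.maximum(firefly[good], 0.0) / renilla[good], dropped


def percent_readthrough(readings: pd.DataFrame) -> ReadthroughEstimate:
    """Compute percent readthrough from a long reading table.

    ``readings`` columns: ``construct`` (stop | sense | blank),
    ``firefly``, ``renilla``, plus optional labels; blank rows may also
    be marked with an ``is_blank`` column.  Blank means are subtracted
    from every signal before ratios are formed.  Replicates whose
    Renilla signal does not exceed the blank are dropped with a flag;
    if a construct loses all replicates the computation errors.
    """
    df = readings.copy()
    if "is_blank" in df.columns:
        blank_mask = df["is_blank"].astype(bool) | (df["construct"] == "blank")
    else:
        blank_mask = df["construct"] == "blank"
    blanks = df[blank_mask]
    signal = df[~blank_mask]
    f_blank = float(blanks["firefly"].mean()) if len(blanks) else 0.0
    r_blank = float(blanks["renilla"].mean()) if len(blanks) else 0.0

    stop = signal[signal["construct"] == "stop"]
    sense = signal[signal["construct"] == "sense"]
    if len(stop) == 0 or len(sense) == 0:
        raise ValueError("need at least one stop and one sense reading")

    stop_ratios, stop_dropped = _ratios(stop, f_blank, r_blank)
    sense_ratios, sense_dropped = _ratios(sense, f_blank, r_blank)
    n_dropped = stop_dropped + sense_dropped
    if stop_ratios.size == 0 or sense_ratios.size == 0:
        raise ValueError("all replicates dropped after blank subtraction")
    sense_mean = sense_ratios.mean()
    if sense_mean <= 0:
        raise ValueError("sense-construct ratio non-positive after blank subtraction")

    percent = 100.0 * stop_ratios.mean() / sense_mean
    # Dispersion: SD of the per-replicate stop ratios on the percent scale
    # (each stop replicate normalized by the sense-construct mean).
    per_replicate = 100.0 * stop_ratios / sense_mean
    sd = float(per_replicate.std(ddof=1)) if per_replicate.size > 1 else 0.0

    n = int(stop_ratios.size)
    flag = ""
    if n_dropped:
        flag = f"{n_dropped} replicates dropped"
    if n < MIN_MEASUREMENTS:
        flag = (flag + "; " if flag else "") + (
            f"fewer than {MIN_MEASUREMENTS} measurements (n={n})"
        )
    return ReadthroughEstimate(float(percent), float(sd), n, n_dropped, flag)


def readthrough_fold_change(
    mutant: ReadthroughEstimate, wildtype: ReadthroughEstimate
) -> float:
    """Fold increase of readthrough, e.g. sup35 over wildtype."""
    if wildtype.percent <= 0:
        raise ValueError("wildtype percent readthrough must be > 0")
    return mutant.percent / wildtype.percent
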