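"""Synthetic segregant pools, selections, array intensities and assays.

This module generates every raw data type the pipeline consumes, with
known ground truth:

* haploid segregant pools from a BY x RM cross (meiotic mosaic genotypes),
* one round of fitness-proportional selection driven by planted QTLs,
* two-channel allele-specific array intensities against a common
  BY/RM-diploid reference,
* microplate OD600 growth curves (logistic + additive noise),
* paired dual-luciferase readings for stop- and sense-codon reporters.

Alleles are coded 1 = BY, 0 = RM throughout.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel, MarkerMap

BY, RM = 1, 0
CROSSES = ("wildtype", "sup35")


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class QTLSpec:
    """A planted QTL: marker index plus per-cross selective advantages.

    ``effect_wt`` / ``effect_mut`` are the selective advantage of the BY
    allele in the wildtype and sup35 crosses respectively (signed; a
    negative value favours the RM allele).  A readthrough-dependent QTL
    has ``effect_wt != effect_mut``; a shared QTL has equal effects.
    """

    marker: int
    effect_wt: float
    effect_mut: float

    def effect(self, cross: str) -> float:
        if cross not in CROSSES:
            raise ValueError(f"cross must be one of {CROSSES}, got {cross!r}")
        return self.effect_wt if cross == "wildtype" else self.effect_mut

    @property
    def readthrough_dependent(self) -> bool:
        return self.effect_wt != self.effect_mut


@dataclass
class SegregantPool:
    """A pool of haploid segregants: genotype matrix + per-segregant fitness.

    ``genotypes`` is (n_segregants, n_markers) int8 with 1 = BY, 0 = RM;
    each row is a mosaic of parental blocks within every chromosome.
    """

    genotypes: np.ndarray
    fitness: np.ndarray
    genome: GenomeModel

    @property
    def n_segregants(self) -> int:
        return self.genotypes.shape[0]

    def allele_frequency(self) -> np.ndarray:
        """Per-marker BY-allele frequency."""
        return self.genotypes.mean(axis=0, dtype=np.float64)


def simulate_cross(
    genome: GenomeModel, n_segregants: int, seed=None
) -> SegregantPool:
    """Simulate haploid segregants of a BY x RM cross.

    Each segregant's chromosome starts from a Mendelian (fair-coin)
    parental allele and accumulates ``Poisson(recombination_rate)``
    crossovers at positions uniform in bp — a no-interference crossover
    model.  With ``recombination_rate = 0`` every chromosome is wholly
    BY or wholly RM.
    """
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    rng = as_rng(seed)
    mm = genome.markers
    geno = np.empty((n_segregants, mm.n_markers), dtype=np.int8)
    for chrom, sl in mm.iter_chromosomes():
        pos = mm.positions[sl]
        length = genome.chrom_length(chrom)
        start = rng.integers(0, 2, size=n_segregants).astype(np.int8)
        n_co = rng.poisson(genome.recombination_rate, size=n_segregants)
        breakpoints = rng.uniform(0, length, size=int(n_co.sum()))
        seg_of_break = np.repeat(np.arange(n_segregants), n_co)
        # A breakpoint at b flips all markers with pos >= b: accumulate
        # flip counts into the marker bin each breakpoint lands in front of.
        bins = np.searchsorted(pos, breakpoints, side="left")
        flips = np.zeros((n_segregants, len(pos) + 1), dtype=np.int8)
        np.add.at(flips, (seg_of_break, bins), 1)
        parity = np.cumsum(flips[:, :-1], axis=1, dtype=np.int32)
        geno[:, sl] = (start[:, None] + parity) % 2
    return SegregantPool(geno, np.ones(n_segregants), genome)


def apply_selection(
    pool: SegregantPool,
    qtls: list[QTLSpec],
    cross: str,
    n_survivors: int,
    seed=None,
) -> SegregantPool:
    """One round of fitness-proportional selection without replacement.

    Fitness is multiplicative across QTLs: a segregant carrying the BY
    allele at a QTL with effect ``e`` gains a factor ``1 + e``, an RM
    carrier gains ``1 - e`` (so ``|e| < 1`` is required).  Survivors are
    drawn without replacement with probability proportional to fitness
    (Gumbel top-k, i.e. Plackett–Luce successive sampling), standing in
    for two days of competitive growth on a selection plate.
    """
    if cross not in CROSSES:
        raise ValueError(f"cross must be one of {CROSSES}, got {cross!r}")
    n = pool.n_segregants
    if not 1 <= n_survivors <= n:
        raise ValueError("n_survivors must be in [1, pool size]")
    rng = as_rng(seed)
    log_fitness = np.zeros(n)
    for q in qtls:
        e = q.effect(cross)
        if abs(e) >= 1:
            raise ValueError(
                f"|effect| must be < 1 (fitness would be non-positive); got {e}"
            )
        is_by = pool.genotypes[:, q.marker] == BY
        log_fitness += np.where(is_by, np.log1p(e), np.log1p(-e))
    keys = log_fitness + rng.gumbel(size=n)
    idx = np.sort(np.argpartition(-keys, n_survivors - 1)[:n_survivors])
    return SegregantPool(
        pool.genotypes[idx], np.exp(log_fitness[idx]), pool.genome
    )


def expected_selection_frequency(
    pool: SegregantPool, qtls: list[QTLSpec], cross: str
) -> np.ndarray:
    """Fitness-weighted BY-allele frequency of the pool.

    This is the expected post-selection frequency under
    probability-proportional-to-fitness sampling; tests use it as a
    direct-computation oracle for :func:`apply_selection`.
    """
    w = np.ones(pool.n_segregants)
    for q in qtls:
        e = q.effect(cross)
        is_by = pool.genotypes[:, q.marker] == BY
        w *= np.where(is_by, 1.0 + e, 1.0 - e)
    w = w / w.sum()
    return w @ pool.genotypes


# ---------------------------------------------------------------------------
# Array hybridization
# ---------------------------------------------------------------------------

def synthesize_hybridization(
    pool: SegregantPool,
    noise_sd: float = 0.0,
    dye_bias: float = 0.0,
    seed=None,
    scale: float = 1000.0,
    affinity_sd: float = 0.3,
    freq_floor: float = 1e-3,
) -> pd.DataFrame:
    """Hybridize a pool onto the allele-specific two-channel array.

    Per marker the array carries one BY-specific and one RM-specific
    probe; the sample channel intensity is proportional to the pool's
    BY- (resp. RM-) allele frequency and the common-reference channel
    (a BY/RM diploid) is proportional to 0.5.

    Noise model (all log10-scale, multiplicative):

    * ``affinity_sd`` — per-probe affinity shared by both channels of
      the same probe (sequence effects; cancels in sample/reference
      ratios),
    * ``noise_sd`` — per-probe measurement noise on the sample channel,
      so a computed skew value carries noise sd ``sqrt(2) * noise_sd``,
    * ``dye_bias`` — one global log10 offset on the sample channel (the
      Cy3/Cy5 imbalance normalization must remove).

    Frequencies are clipped to ``[freq_floor, 1 - freq_floor]`` so all
    intensities stay strictly positive.

    Returns a frame with columns
    ``marker_id, sample_BY, sample_RM, ref_BY, ref_RM``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = as_rng(seed)
    p = np.clip(pool.allele_frequency(), freq_floor, 1.0 - freq_floor)
    m = len(p)
    aff_by = 10.0 ** (affinity_sd * rng.standard_normal(m))
    aff_rm = 10.0 ** (affinity_sd * rng.standard_normal(m))
    noise_by = 10.0 ** (noise_sd * rng.standard_normal(m))
    noise_rm = 10.0 ** (noise_sd * rng.standard_normal(m))
    bias = 10.0 ** dye_bias
    return pd.DataFrame(
        {
            "marker_id": pool.genome.markers.frame["marker_id"].to_numpy(),
            "sample_BY": scale * p * aff_by * bias * noise_by,
            "sample_RM": scale * (1.0 - p) * aff_rm * bias * noise_rm,
            "ref_BY": scale * 0.5 * aff_by,
            "ref_RM": scale * 0.5 * aff_rm,
        }
    )


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def synthesize_growth_curve(
    rate: float,
    od0: float = 0.02,
    carrying_capacity: float = 1.2,
    interval_min: float = 30.0,
    duration_h: float = 20.0,
    noise_sd: float = 0.003,
    seed=None,
    **labels,
):
    """Simulate a microplate OD600 time series.

    Logistic growth ``OD(t) = K od0 e^{rt} / (K + od0 (e^{rt} - 1))``
    sampled every ``interval_min`` minutes for ``duration_h`` hours with
    additive Gaussian noise of sd ``noise_sd`` (plate-reader noise is
    approximately absolute at the low ODs where rate fitting happens).
    ``carrying_capacity=np.inf`` gives exact exponential growth.
    """
    from .growth import GrowthCurve  # local import to avoid a cycle

    if duration_h < 0 or interval_min <= 0:
        raise ValueError("duration must be >= 0 and interval > 0")
    if not 0 < od0 < carrying_capacity:
        raise ValueError("need 0 < od0 < carrying_capacity")
    rng = as_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    if np.isinf(carrying_capacity):
        od = od0 * np.exp(rate * t)
    else:
        K = carrying_capacity
        growth = np.exp(rate * t)
        od = K * od0 * growth / (K + od0 * (growth - 1.0))
    od = od + noise_sd * rng.standard_normal(len(t))
    return GrowthCurve(time_h=t, od=np.maximum(od, 0.0), **labels)


# ---------------------------------------------------------------------------
# Dual luciferase
# ---------------------------------------------------------------------------

def synthesize_luciferase(
    true_readthrough_pct: float,
    renilla_mean: float = 1e5,
    noise_cv: float = 0.1,
    n_replicates: int = 8,
    n_blanks: int = 4,
    sense_ratio: float = 1.0,
    blank_frac: float = 1e-3,
    seed=None,
    strain: str = "",
) -> pd.DataFrame:
    """Simulate paired stop-/sense-construct dual-luciferase readings.

    The sense construct's firefly/Renilla ratio is fixed at
    ``sense_ratio``; the stop construct's ratio is
    ``sense_ratio * true_readthrough_pct / 100``.  Each reading carries
    multiplicative noise of coefficient of variation ``noise_cv`` and an
    additive reagent background (``blank_frac * renilla_mean``) that the
    blank rows measure, mirroring no-lysate negative controls.

    Returns a long frame with columns
    ``construct, firefly, renilla, strain, replicate, is_blank``.
    """
    if not 0 <= true_readthrough_pct <= 100:
        raise ValueError("true_readthrough_pct must be in [0, 100]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = as_rng(seed)
    bg = blank_frac * renilla_mean

    def noisy(mean, size):
        return mean * (1.0 + noise_cv * rng.standard_normal(size))

    rows = []
    for construct, ratio in (
        ("stop", sense_ratio * true_readthrough_pct / 100.0),
        ("sense", sense_ratio),
    ):
        firefly = noisy(renilla_mean * ratio, n_replicates) + bg
        renilla = noisy(renilla_mean, n_replicates) + bg
        for r in range(n_replicates):
            rows.append(
                (construct, firefly[r], renilla[r], strain, r + 1, False)
            )
    blank_f = np.abs(noisy(bg, n_blanks))
    blank_r = np.abs(noisy(bg, n_blanks))
    for r in range(n_blanks):
        rows.append(("blank", blank_f[r], blank_r[r], "", r + 1, True))
    return pd.DataFrame(
        rows,
        columns=["construct", "firefly", "renilla", "strain", "replicate", "is_blank"],
    )


# ---------------------------------------------------------------------------
# Whole X-QTL experiments
# ---------------------------------------------------------------------------

@dataclass
class XqtlExperiment:
    """Raw intensity tables of a two-cross X-QTL experiment.

    ``tables[(cross, arm, rep)]`` holds one array's intensity frame,
    with ``arm`` one of ``selection`` (growth on condition plates),
    ``control`` (whole unselected population), ``ypd_selection`` /
    ``ypd_control`` (the matched rich-medium experiment used to build
    the null differential for FDR calibration).
    """

    genome: GenomeModel
    qtls: list[QTLSpec]
    tables: dict[tuple[str, str, int], pd.DataFrame]
    n_replicates: int

    @property
    def markers(self) -> MarkerMap:
        return self.genome.markers


def simulate_xqtl_experiment(
    genome: GenomeModel,
    qtls: list[QTLSpec],
    n_segregants: int = 10_000,
    n_survivors: int = 2_000,
    noise_sd: float = 0.1,
    dye_bias: float = 0.0,
    n_replicates: int = 2,
    seed=None,
    with_ypd_null: bool = True,
) -> XqtlExperiment:
    """Simulate the full paired-cross X-QTL design.

    For each cross (wildtype, sup35) and each biological replicate an
    independent segregant pool is built; the condition arm selects
    ``n_survivors`` segregants under the planted QTL effects, the
    control arm hybridizes the whole pool.  When ``with_ypd_null`` is
    set, a neutral (no-QTL) selection of the same pool plus its own
    control hybridization emulate the rich-medium X-QTL run from which
    the empirical-FDR null differential is built.
    """
    rng = as_rng(seed)
    tables: dict[tuple[str, str, int], pd.DataFrame] = {}
    for cross in CROSSES:
        for rep in range(1, n_replicates + 1):
            pool = simulate_cross(genome, n_segregants, rng)
            selected = apply_selection(pool, qtls, cross, n_survivors, rng)

            def hyb(p):
                return synthesize_hybridization(
                    p, noise_sd=noise_sd, dye_bias=dye_bias, seed=rng
                )

            tables[(cross, "selection", rep)] = hyb(selected)
            tables[(cross, "control", rep)] = hyb(pool)
            if with_ypd_null:
                neutral = apply_selection(pool, [], cross, n_survivors, rng)
                tables[(cross, "ypd_selection", rep)] = hyb(neutral)
                tables[(cross, "ypd_control", rep)] = hyb(pool)
    return XqtlExperiment(genome, list(qtls), tables, n_replicates)
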