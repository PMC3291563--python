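"""Genome model and marker map for a BY x RM segregant cross.

The marker map is the shared genomic coordinate system of the whole
pipeline: every skew track, smoothed track and locus call is aligned to
it.  Coordinates are 1-based base pairs, markers sorted by (chromosome,
position) with unique positions per chromosome — the convention used by
SGD and by allele-specific genotyping arrays for this cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKER_MAP_COLUMNS = ["chrom", "pos_bp", "marker_id", "by_probe", "rm_probe"]

#: Roman-numeral chromosome names of the S. cerevisiae nuclear genome.
YEAST_CHROMOSOMES = [
    "chrI", "chrII", "chrIII", "chrIV", "chrV", "chrVI", "chrVII", "chrVIII",
    "chrIX", "chrX", "chrXI", "chrXII", "chrXIII", "chrXIV", "chrXV", "chrXVI",
]


class MarkerMapError(ValueError):
    """Raised when a marker table violates the map invariants."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP markers with chromosome, position and probe identifiers.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``chrom, pos_bp, marker_id, by_probe, rm_probe``.  Rows
        must be sorted by chromosome (in first-appearance order) and by
        strictly increasing position within each chromosome.

    Notes
    -----
    Chromosome order is the order of first appearance in ``frame``; it is
    preserved, not re-sorted lexicographically (``chrII`` before ``chrX``).
    """

    frame: pd.DataFrame
    _chrom_bounds: dict[str, tuple[int, int]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in MARKER_MAP_COLUMNS if c not in df.columns]
        if missing:
            raise MarkerMapError(f"marker map missing columns: {missing}")
        if len(df) == 0:
            raise MarkerMapError("marker map is empty")
        df = df.reset_index(drop=True)
        bounds: dict[str, tuple[int, int]] = {}
        chroms = df["chrom"].to_numpy()
        pos = df["pos_bp"].to_numpy()
        start = 0
        for i in range(1, len(df) + 1):
            if i == len(df) or chroms[i] != chroms[start]:
                name = chroms[start]
                if name in bounds:
                    raise MarkerMapError(
                        f"chromosome {name!r} appears in non-contiguous blocks"
                    )
                block = pos[start:i]
                if np.any(np.diff(block) <= 0):
                    raise MarkerMapError(
                        f"positions not strictly increasing on {name!r}"
                    )
                if block[0] < 1:
                    raise MarkerMapError("positions are 1-based; got < 1")
                bounds[name] = (start, i)
                start = i
        if df["marker_id"].duplicated().any():
            raise MarkerMapError("duplicate marker_id values")
        object.__setattr__(self, "frame", df)
        object.__setattr__(self, "_chrom_bounds", bounds)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_bounds)

    @property
    def positions(self) -> np.ndarray:
        return self.frame["pos_bp"].to_numpy()

    @property
    def marker_ids(self) -> pd.Index:
        return pd.Index(self.frame["marker_id"])

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self._chrom_bounds[chrom]
        return slice(lo, hi)

    def iter_chromosomes(self):
        """Yield ``(chrom, slice)`` pairs in map order."""
        for chrom, (lo, hi) in self._chrom_bounds.items():
            yield chrom, slice(lo, hi)

    def same_map(self, other: "MarkerMap") -> bool:
        """True if both maps describe the same markers in the same order."""
        if self is other:
            return True
        a, b = self.frame, other.frame
        return len(a) == len(b) and bool(
            (a["marker_id"].to_numpy() == b["marker_id"].to_numpy()).all()
            and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["pos_bp"].to_numpy() == b["pos_bp"].to_numpy()).all()
        )


@dataclass(frozen=True)
class GenomeModel:
    """A simulated genome: chromosome sizes, marker map, genetic map length.

    Parameters
    ----------
    chromosomes : list of (name, length_bp)
    markers : MarkerMap
        Every chromosome must carry at least one marker, and all marker
        positions must fall inside the chromosome.
    recombination_rate : float
        Expected crossovers per chromosome per meiosis (Poisson mean of
        the no-interference crossover model).  The default genome uses
        2.9, matching the ~4,400 cM yeast genetic map spread over 16
        chromosomes.
    """

    chromosomes: list[tuple[str, int]]
    markers: MarkerMap
    recombination_rate: float = 2.9

    def __post_init__(self) -> None:
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        lengths = dict(self.chromosomes)
        if set(self.markers.chromosomes) - set(lengths):
            raise MarkerMapError("marker map names chromosomes absent from genome")
        for chrom, sl in self.markers.iter_chromosomes():
            pos = self.markers.positions[sl]
            if pos[-1] > lengths[chrom]:
                raise MarkerMapError(f"marker beyond end of {chrom!r}")
        for chrom, _ in self.chromosomes:
            if chrom not in self.markers.chromosomes:
                raise MarkerMapError(f"chromosome {chrom!r} has no markers")

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]


def default_genome(
    n_markers: int = 18_000,
    n_chromosomes: int = 16,
    total_bp: int = 12_000_000,
    recombination_rate: float = 2.9,
) -> GenomeModel:
    """Build the standard synthetic genome.

    16 equal chromosomes totalling ~12 Mb with ``n_markers`` markers placed
    uniformly — the marker density of an ~18,000-SNP allele-specific
    genotyping array on the ~12 Mb yeast genome.
    """
    names = (
        YEAST_CHROMOSOMES[:n_chromosomes]
        if n_chromosomes <= len(YEAST_CHROMOSOMES)
        else [f"chr{i + 1}" for i in range(n_chromosomes)]
    )
    chrom_len = total_bp // n_chromosomes
    base, extra = divmod(n_markers, n_chromosomes)
    rows = []
    k = 0
    for i, name in enumerate(names):
        m = base + (1 if i < extra else 0)
        # Evenly spaced, 1-based, strictly inside the chromosome.  Rounding
        # can tie adjacent positions only when m approaches chrom_len; bump
        # ties forward to keep positions strictly increasing.
        pos = np.linspace(1, chrom_len, num=m).round().astype(np.int64)
        for j in range(1, m):
            if pos[j] <= pos[j - 1]:
                pos[j] = pos[j - 1] + 1
        for p in pos:
            rows.append((name, int(p), f"mrk_{k:05d}", f"byp_{k:05d}", f"rmp_{k:05d}"))
            k += 1
    frame = pd.DataFrame(rows, columns=MARKER_MAP_COLUMNS)
    markers = MarkerMap(frame)
    return GenomeModel(
        chromosomes=[(n, chrom_len) for n in names],
        markers=markers,
        recombination_rate=recombination_rate,
    )
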