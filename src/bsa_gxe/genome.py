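"""Genome maps for a haploid two-parent yeast cross.

A :class:`GenomeMap` holds ordered chromosome lengths, per-chromosome marker
positions (1-based bp), and the physical-to-genetic scale (bp per centiMorgan).
The default scale of 2,200 bp/cM is the genome-wide average for the BY x RM
cross and is the value used throughout the mapping model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Nuclear chromosome lengths of the S. cerevisiae reference genome (sacCer3),
#: in bp.  Sixteen chromosomes; the mitochondrial genome is excluded.
SACCER3_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chrI", 230_218),
    ("chrII", 813_184),
    ("chrIII", 316_620),
    ("chrIV", 1_531_933),
    ("chrV", 576_874),
    ("chrVI", 270_161),
    ("chrVII", 1_090_940),
    ("chrVIII", 562_643),
    ("chrIX", 439_888),
    ("chrX", 745_751),
    ("chrXI", 666_816),
    ("chrXII", 1_078_177),
    ("chrXIII", 924_431),
    ("chrXIV", 784_333),
    ("chrXV", 1_091_291),
    ("chrXVI", 948_066),
)

#: Default bp per centiMorgan for the BY x RM cross.
DEFAULT_BP_PER_CM = 2_200.0

#: Marker spacing (bp) that reproduces the density of the ~18.9k high-confidence
#: SNP panel over the 12.07-Mb nuclear genome.
DEFAULT_MARKER_SPACING = 640


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome lengths, marker positions, and genetic map scale.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    markers
        Mapping from chromosome name to a sorted array of 1-based marker
        positions in bp.  Positions must be strictly increasing and lie in
        ``[1, length]``.
    bp_per_cM
        Physical distance corresponding to one centiMorgan.
    """

    chromosomes: tuple[tuple[str, int], ...]
    markers: Mapping[str, np.ndarray] = field(default_factory=dict)
    bp_per_cM: float = DEFAULT_BP_PER_CM

    def __post_init__(self) -> None:
        if self.bp_per_cM <= 0:
            raise ValueError("bp_per_cM must be positive")
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        clean: dict[str, np.ndarray] = {}
        for name, pos in self.markers.items():
            if name not in lengths:
                raise ValueError(f"markers given for unknown chromosome {name}")
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"marker positions for {name} must be 1-D")
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError(f"marker positions on {name} must be strictly increasing")
            if arr.size and (arr[0] < 1 or arr[-1] > lengths[name]):
                raise ValueError(f"marker positions on {name} outside [1, length]")
            clean[name] = arr
        object.__setattr__(self, "markers", clean)

    # -- convenience accessors -------------------------------------------------

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        return self.lengths[chrom]

    def markers_of(self, chrom: str) -> np.ndarray:
        arr = self.markers.get(chrom)
        if arr is None or arr.size == 0:
            raise ValueError(f"chromosome {chrom} has an empty marker set")
        return arr

    @property
    def n_markers(self) -> int:
        return int(sum(len(v) for v in self.markers.values()))

    def morgans(self, bp: float) -> float:
        """Convert a physical distance in bp to Morgans."""
        return bp / (self.bp_per_cM * 100.0)


def evenly_spaced_markers(length: int, spacing: int, offset: int | None = None) -> np.ndarray:
    """1-based marker positions every ``spacing`` bp, starting mid-interval."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    start = (spacing // 2) if offset is None else offset
    start = max(start, 1)
    return np.arange(start, length + 1, spacing, dtype=np.int64)


def saccer3_genome(marker_spacing: int = DEFAULT_MARKER_SPACING,
                   bp_per_cM: float = DEFAULT_BP_PER_CM) -> GenomeMap:
    """Full 16-chromosome genome with evenly spaced synthetic markers."""
    markers = {name: evenly_spaced_markers(length, marker_spacing)
               for name, length in SACCER3_CHROMOSOMES}
    return GenomeMap(SACCER3_CHROMOSOMES, markers, bp_per_cM)


def toy_genome(lengths: Sequence[int] = (600_000, 450_000),
               marker_spacing: int = DEFAULT_MARKER_SPACING,
               bp_per_cM: float = DEFAULT_BP_PER_CM) -> GenomeMap:
    """Small multi-chromosome genome for simulations and tests.

    Chromosome names follow the reference convention (``chrI``, ``chrII``, ...).
    """
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    chroms = tuple((f"chr{roman[i]}", int(L)) for i, L in enumerate(lengths))
    markers = {name: evenly_spaced_markers(length, marker_spacing)
               for name, length in chroms}
    return GenomeMap(chroms, markers, bp_per_cM)


def n_bins(length: int, width: int) -> int:
    """Number of half-open bins of ``width`` covering ``length`` bp."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    return math.ceil(length / width)
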