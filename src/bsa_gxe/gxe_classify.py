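"""Locus-level genotype-by-environment classification and genome-wide summary.

Each locus detected in both replicates of the baseline (SC) or of another
environment is compared across the pair of environments:

* **presence/absence** — the locus is present in both replicates of one
  environment and no QTL peak lies within 100 kb in either replicate of the
  other environment;
* **sign change** — a locus within 100 kb in the other environment (in one or
  both of its replicates) has the opposite effect direction;
* **no GxE** — a locus within 100 kb has the same direction (magnitude
  differences are deliberately not classified, since the sorted-pool design
  cannot detect them reliably).

Genome-wide clustering is summarized by tiling the chromosomes into 100-kb
bins, counting QTL peaks and GxE calls per bin, rank-correlating the two
counts over occupied bins, and testing whether the RM allele raises activity
more often than the BY allele with an exact binomial test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import GenomeMap
from .pool_mapping import QtlRecord
from .qtl_catalog import MergedQtl, MATCH_DISTANCE_BP

PRESENCE_ABSENCE = "presence_absence"
SIGN_CHANGE = "sign_change"
NO_GXE = "no_gxe"

BIN_WIDTH_BP = 100_000


@dataclass
class GxeCall:
    """One pairwise baseline-vs-environment locus comparison."""

    reporter: str
    env_pair: tuple[str, str]
    chrom: str
    anchor_peak: float
    category: str
    anchor_env: str                 # environment in which the anchor has both-replicate support
    support_other: str              # "both" | "single" | "none"
    sign_anchor: str
    sign_other: str | None


def _peaks_near(chrom: str, peak: float, records: Sequence[QtlRecord] | Sequence[MergedQtl],
                max_distance: int) -> list:
    return [r for r in records
            if r.chrom == chrom and abs(r.peak - peak) <= max_distance]


def classify_pairwise(baseline_merged: Sequence[MergedQtl],
                      baseline_replicates: Sequence[QtlRecord],
                      env_merged: Sequence[MergedQtl],
                      env_replicates: Sequence[QtlRecord],
                      reporter: str = "",
                      baseline_name: str = "SC", env_name: str = "E",
                      max_distance: int = MATCH_DISTANCE_BP) -> list[GxeCall]:
    """Classify each both-replicate locus of either environment.

    ``*_merged`` are the reconciled loci (only those with both-replicate
    support anchor a comparison); ``*_replicates`` are the per-replicate QTL
    lists used to decide whether *any* peak exists within 100 kb in the other
    environment.  When both environments carry a both-replicate locus within
    100 kb, the pair is deduplicated to a single call anchored in the
    baseline.  Loci with single-replicate support in both environments are
    not classified.
    """
    base_both = [q for q in baseline_merged if q.replicate_support == "both"]
    env_both = [q for q in env_merged if q.replicate_support == "both"]

    # pair both-replicate loci across environments (nearest peak wins)
    pairs = []
    for i, a in enumerate(base_both):
        for j, b in enumerate(env_both):
            if a.chrom == b.chrom and abs(a.peak - b.peak) <= max_distance:
                pairs.append((abs(a.peak - b.peak), i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    paired1: dict[int, int] = {}
    paired2: dict[int, int] = {}
    for d, i, j in pairs:
        if i in paired1 or j in paired2:
            continue
        paired1[i] = j
        paired2[j] = i

    calls: list[GxeCall] = []

    def one_sided(anchor: MergedQtl, anchor_env: str, other_env: str,
                  other_reps: Sequence[QtlRecord]) -> GxeCall:
        near = _peaks_near(anchor.chrom, anchor.peak, other_reps, max_distance)
        if not near:
            return GxeCall(reporter, (baseline_name, env_name), anchor.chrom,
                           anchor.peak, PRESENCE_ABSENCE, anchor_env, "none",
                           anchor.sign, None)
        nearest = min(near, key=lambda r: abs(r.peak - anchor.peak))
        support = "both" if len({r.replicate for r in near}) >= 2 else "single"
        category = SIGN_CHANGE if nearest.sign != anchor.sign else NO_GXE
        return GxeCall(reporter, (baseline_name, env_name), anchor.chrom,
                       anchor.peak, category, anchor_env, support,
                       anchor.sign, nearest.sign)

    for i, a in enumerate(base_both):
        if i in paired1:
            b = env_both[paired1[i]]
            category = SIGN_CHANGE if a.sign != b.sign else NO_GXE
            calls.append(GxeCall(reporter, (baseline_name, env_name), a.chrom,
                                 a.peak, category, baseline_name, "both",
                                 a.sign, b.sign))
        else:
            calls.append(one_sided(a, baseline_name, env_name, env_replicates))
    for j, b in enumerate(env_both):
        if j in paired2:
            continue  # deduplicated: already called from the baseline side
        calls.append(one_sided(b, env_name, baseline_name, baseline_replicates))
    return calls


# ---------------------------------------------------------------------------
# Genome bins
# ---------------------------------------------------------------------------

@dataclass
class GenomeBins:
    """Half-open genomic bins of fixed width with per-bin counts."""

    chroms: list[str]
    starts: np.ndarray              # 0-based inclusive bin starts
    width: int
    qtl_count: np.ndarray
    gxe_count: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.chroms)


def make_bins(genome: GenomeMap, width: int = BIN_WIDTH_BP) -> GenomeBins:
    """Tile every chromosome with half-open bins ``[k*width, (k+1)*width)``.

    The final bin of each chromosome may be partial; the total bin count is
    the sum over chromosomes of ``ceil(length / width)``.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    chroms: list[str] = []
    starts: list[int] = []
    for name, length in genome.chromosomes:
        nb = math.ceil(length / width)
        chroms.extend([name] * nb)
        starts.extend(k * width for k in range(nb))
    n = len(chroms)
    return GenomeBins(chroms, np.asarray(starts, dtype=np.int64), width,
                      np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64))


def _bin_index(bins: GenomeBins, genome: GenomeMap, chrom: str, peak: float,
               label: str) -> int:
    length = genome.lengths.get(chrom)
    if length is None or not (1 <= peak <= length):
        raise ValueError(f"{label}: peak {chrom}:{peak} outside the genome")
    k = int((peak - 1) // bins.width)  # 1-based position -> 0-based coordinate
    for idx, (c, s) in enumerate(zip(bins.chroms, bins.starts)):
        if c == chrom and s == k * bins.width:
            return idx
    raise ValueError(f"{label}: no bin for {chrom}:{peak}")


def count_per_bin(bins: GenomeBins, genome: GenomeMap,
                  qtls: Sequence[MergedQtl] | Sequence[QtlRecord] = (),
                  calls: Sequence[GxeCall] = ()) -> GenomeBins:
    """Increment per-bin QTL and GxE-call counts (one bin per peak)."""
    for q in qtls:
        bins.qtl_count[_bin_index(bins, genome, q.chrom, q.peak, "QTL")] += 1
    for c in calls:
        bins.gxe_count[_bin_index(bins, genome, c.chrom, c.anchor_peak, "GxE call")] += 1
    return bins


def bin_correlation(bins: GenomeBins) -> tuple[float, float, int]:
    """Spearman correlation of QTL and GxE counts over bins with any QTL.

    Ties get average ranks; the p-value uses the t approximation.  Returns
    (rho, p, number of qualifying bins); fewer than 3 qualifying bins is an
    error.
    """
    mask = bins.qtl_count >= 1
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need >= 3 bins with at least one QTL")
    rho, p = stats.spearmanr(bins.qtl_count[mask], bins.gxe_count[mask])
    return float(rho), float(p), n


def direction_binomial_test(qtls: Sequence[MergedQtl] | Sequence[QtlRecord]) -> tuple[float, int, int]:
    """Exact two-sided binomial test of RM-increases-activity against 1/2.

    Counts loci with positive allele-frequency difference (RM allele raises
    activity) among all loci; two-sided by the minimum-likelihood method.
    Returns (p, k, n).
    """
    if len(qtls) == 0:
        raise ValueError("no QTLs to test")
    k = int(sum(1 for q in qtls if q.daf > 0))
    n = len(qtls)
    res = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return float(res.pvalue), k, n
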