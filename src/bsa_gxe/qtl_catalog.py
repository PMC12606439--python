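"""Reconciling QTLs across biological replicates and across studies.

Two QTLs from independent replicate crosses are the same locus when they lie
on the same chromosome with peaks within 100 kb and have the same effect
direction (sign of the high-minus-low allele-frequency difference).  Matched
pairs are merged by averaging peak, interval, LOD, and effect; unmatched
records keep single-replicate support.  The same 100-kb peak-distance rule
flags overlap with loci from prior studies, and two-sample t-tests compare
the LOD and absolute effect of shared versus study-specific loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pool_mapping import QtlRecord

MATCH_DISTANCE_BP = 100_000


@dataclass
class MergedQtl:
    """A locus after replicate reconciliation."""

    chrom: str
    peak: float
    ci_left: float
    ci_right: float
    lod: float
    daf: float
    sign: str
    replicate_support: str          # "both" | "single"
    sources: tuple[str, ...]
    reporter: str = ""
    environment: str = ""


def _merge_pair(a: QtlRecord, b: QtlRecord) -> MergedQtl:
    return MergedQtl(
        chrom=a.chrom,
        peak=(a.peak + b.peak) / 2.0,
        ci_left=(a.ci_left + b.ci_left) / 2.0,
        ci_right=(a.ci_right + b.ci_right) / 2.0,
        lod=(a.lod + b.lod) / 2.0,
        daf=(a.daf + b.daf) / 2.0,
        sign=a.sign,
        replicate_support="both",
        sources=(a.replicate, b.replicate),
        reporter=a.reporter,
        environment=a.environment,
    )


def _single(q: QtlRecord) -> MergedQtl:
    return MergedQtl(chrom=q.chrom, peak=q.peak, ci_left=q.ci_left,
                     ci_right=q.ci_right, lod=q.lod, daf=q.daf, sign=q.sign,
                     replicate_support="single", sources=(q.replicate,),
                     reporter=q.reporter, environment=q.environment)


def match_replicates(qtls_rep1: Sequence[QtlRecord],
                     qtls_rep2: Sequence[QtlRecord],
                     max_distance: int = MATCH_DISTANCE_BP) -> list[MergedQtl]:
    """Greedy nearest-peak matching of two replicates' QTL lists.

    Candidate pairs must share a chromosome, lie within ``max_distance`` of
    each other peak-to-peak, and agree in sign.  Pairs are accepted in order
    of increasing peak distance, each QTL used at most once (nearest peak
    wins on multi-way ties).  Matched pairs are averaged; the rest pass
    through with single-replicate support.
    """
    pairs = []
    for i, a in enumerate(qtls_rep1):
        for j, b in enumerate(qtls_rep2):
            if a.chrom != b.chrom or a.sign != b.sign:
                continue
            d = abs(a.peak - b.peak)
            if d <= max_distance:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    merged: list[MergedQtl] = []
    for d, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        merged.append(_merge_pair(qtls_rep1[i], qtls_rep2[j]))
    for i, a in enumerate(qtls_rep1):
        if i not in used1:
            merged.append(_single(a))
    for j, b in enumerate(qtls_rep2):
        if j not in used2:
            merged.append(_single(b))
    merged.sort(key=lambda q: (q.chrom, q.peak))
    return merged


def cross_study_overlap(merged_both: Sequence[MergedQtl],
                        prior_rep1: Sequence[QtlRecord],
                        prior_rep2: Sequence[QtlRecord],
                        max_distance: int = MATCH_DISTANCE_BP
                        ) -> list[dict]:
    """Flag loci whose peak lies within 100 kb of a prior-study QTL.

    A locus is shared when at least one prior replicate has a QTL on the same
    chromosome within ``max_distance`` of its peak; sign concordance with the
    nearest such prior QTL is recorded separately.
    """
    out = []
    prior = list(prior_rep1) + list(prior_rep2)
    for q in merged_both:
        near = [p for p in prior
                if p.chrom == q.chrom and abs(p.peak - q.peak) <= max_distance]
        shared = len(near) > 0
        concordant = None
        if shared:
            nearest = min(near, key=lambda p: abs(p.peak - q.peak))
            concordant = (nearest.sign == q.sign)
        out.append({"chrom": q.chrom, "peak": q.peak, "lod": q.lod,
                    "daf": q.daf, "shared": shared, "sign_concordant": concordant})
    return out


@dataclass
class GroupComparison:
    """Two-sample t-test between shared and study-specific loci."""

    statistic: float
    pvalue: float
    n_shared: int
    n_unique: int
    computable: bool


def compare_shared_vs_unique(merged: Sequence[MergedQtl],
                             shared_flags: Sequence[bool],
                             equal_var: bool = True
                             ) -> dict[str, GroupComparison]:
    """t-tests on LOD and |daf| between shared and unique loci.

    Returns comparisons keyed ``"lod"`` and ``"abs_daf"``; a group with fewer
    than 2 members makes the result not computable.
    """
    flags = np.asarray(shared_flags, dtype=bool)
    lod = np.array([q.lod for q in merged], dtype=float)
    adaf = np.abs(np.array([q.daf for q in merged], dtype=float))
    out: dict[str, GroupComparison] = {}
    for key, values in (("lod", lod), ("abs_daf", adaf)):
        a, b = values[flags], values[~flags]
        if a.size < 2 or b.size < 2:
            out[key] = GroupComparison(float("nan"), float("nan"),
                                       int(a.size), int(b.size), False)
            continue
        if np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        out[key] = GroupComparison(float(t), float(p), int(a.size), int(b.size), True)
    return out
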