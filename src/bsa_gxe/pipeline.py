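"""End-to-end drivers tying the generator to mapping and classification.

These helpers run the whole chain — simulate a cross, sequence the sorted
pools, map each replicate, reconcile replicates, classify GxE — at the study
conditions, and are used by the analysis scripts, the test suite, and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap, toy_genome
from .simulate import CrossDesign, QtlSpec, simulate_cross
from .pool_mapping import HmmParams, QtlRecord, map_track
from .qtl_catalog import MergedQtl, match_replicates
from .gxe_classify import GxeCall, classify_pairwise

#: Default two-chromosome genome used for simulation studies; marker density
#: mirrors the ~18.9k-SNP panel (one marker per 640 bp).
STUDY_LENGTHS = (600_000, 450_000)


@dataclass
class ReplicatedMapping:
    """Per-replicate and reconciled mapping results for one environment."""

    environment: str
    per_replicate: list[list[QtlRecord]] = field(default_factory=list)
    merged: list[MergedQtl] = field(default_factory=list)

    @property
    def all_replicate_qtls(self) -> list[QtlRecord]:
        return [q for rep in self.per_replicate for q in rep]

    @property
    def both_support(self) -> list[MergedQtl]:
        return [q for q in self.merged if q.replicate_support == "both"]


def study_params(design: CrossDesign, **overrides) -> HmmParams:
    """Mapping-model settings matched to a simulated cross.

    The effective pool size is the number of genomes actually sorted into
    each tail pool — ``ceil(tail_fraction * n_segregants)`` — so both the
    read-information cap and the finite-pool drift kernel reflect the
    simulated pools.
    """
    import math

    pool = math.ceil(design.tail_fraction * design.n_segregants)
    overrides.setdefault("effective_pool_size", float(pool))
    return HmmParams(**overrides)


def map_replicated_cross(genome: GenomeMap, design: CrossDesign, seed: int,
                         environments: tuple[str, ...],
                         params: HmmParams | None = None,
                         n_replicates: int = 2,
                         reporter: str = "rep") -> dict[str, ReplicatedMapping]:
    """Simulate independent replicate crosses and map each environment.

    Each biological replicate is an independent segregant panel from the same
    cross design (independent matings), mirroring the two-replicate design of
    the sorted-pool experiment.  When ``params`` is not given, the model's
    effective pool size is set to the simulated sorted-pool size.
    """
    if params is None:
        params = study_params(design)
    results = {env: ReplicatedMapping(env) for env in environments}
    for r in range(n_replicates):
        data = simulate_cross(genome, design, seed=(seed * n_replicates + r) % (2**31),
                              environments=environments)
        for env in environments:
            _, qtls, _ = map_track(data.counts[env], genome, params,
                                   replicate=f"r{r + 1}", reporter=reporter,
                                   environment=env)
            results[env].per_replicate.append(qtls)
    for env in environments:
        reps = results[env].per_replicate
        merged = match_replicates(reps[0], reps[1]) if len(reps) >= 2 else \
            [  # single replicate: everything passes through unmerged
                m for m in match_replicates(reps[0], [])]
        results[env].merged = merged
    return results


def classify_study(mappings: dict[str, ReplicatedMapping], baseline: str = "SC",
                   reporter: str = "rep") -> list[GxeCall]:
    """Baseline-versus-environment GxE calls for every non-baseline environment."""
    base = mappings[baseline]
    calls: list[GxeCall] = []
    for env, m in mappings.items():
        if env == baseline:
            continue
        calls.extend(classify_pairwise(base.merged, base.all_replicate_qtls,
                                       m.merged, m.all_replicate_qtls,
                                       reporter=reporter, baseline_name=baseline,
                                       env_name=env))
    return calls


def gxe_study_design(n_segregants: int = 5_000, effect: float = 0.75,
                     mean_depth: float = 100.0, seed: int = 0) -> tuple[GenomeMap, CrossDesign]:
    """Cross with one locus of each constructed GxE category.

    Three QTLs on a two-chromosome genome, well separated (> 200 kb):
    presence/absence (effect only in SC), sign change (opposite sign in the
    second environment), and no GxE (same effect in both environments).
    """
    genome = toy_genome(STUDY_LENGTHS)
    qtls = (
        QtlSpec("chrI", 150_000, effect, {"SC": 1.0, "E": 0.0}),     # presence/absence
        QtlSpec("chrI", 480_000, effect, {"SC": 1.0, "E": -1.0}),    # sign change
        QtlSpec("chrII", 220_000, effect, {"SC": 1.0, "E": 1.0}),    # no GxE
    )
    design = CrossDesign(n_segregants=n_segregants, qtls=qtls,
                         mean_depth=mean_depth, seed=seed)
    return genome, design


def single_qtl_design(n_segregants: int = 5_000, effect: float = 0.75,
                      mean_depth: float = 100.0, seed: int = 0,
                      pos: int = 300_000, chrom_index: int = 0) -> tuple[GenomeMap, CrossDesign]:
    """Cross with a single additive QTL, for parameter-recovery checks."""
    genome = toy_genome(STUDY_LENGTHS)
    chrom = genome.chrom_names[chrom_index]
    design = CrossDesign(n_segregants=n_segregants,
                         qtls=(QtlSpec(chrom, pos, effect, {"SC": 1.0}),),
                         mean_depth=mean_depth, seed=seed)
    return genome, design


def null_design(n_segregants: int = 2_000, mean_depth: float = 50.0,
                seed: int = 0) -> tuple[GenomeMap, CrossDesign]:
    """Cross with no QTLs, for null-calibration checks."""
    genome = toy_genome(STUDY_LENGTHS)
    return genome, CrossDesign(n_segregants=n_segregants, qtls=(),
                               mean_depth=mean_depth, seed=seed)
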