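"""Synthetic yeast-cross generator.

Emulates the data-generating process of a bulk-segregant UPS-activity screen:

* a haploid two-parent (BY x RM) cross with Mendelian 50/50 segregation and
  linkage under a Haldane (Poisson, no-interference) crossover process;
* additive QTL effects on a quantitative trait (UPS activity) whose presence
  and sign can differ between environments via per-environment multipliers;
* truncation selection of the phenotypic tails (FACS sorting of the 2% high-
  and low-activity pools by default);
* pooled whole-genome sequencing of the sorted pools with Poisson depth and
  binomial allele sampling at each marker;
* per-cell flow-cytometry event streams for a two-color timer reporter with
  an optional linear acquisition-time drift.

Genotypes are encoded 0 = BY, 1 = RM.  Every stochastic operation takes an
explicit seed; pipeline runs derive per-stage seeds from a master seed by
fixed offsets (:func:`stage_rng`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeMap

BY, RM = 0, 1

# Fixed per-stage offsets for deriving substream seeds from one master seed.
STAGE_GENOTYPES = 1
STAGE_TRAIT = 2
STAGE_COUNTS = 3
STAGE_EVENTS = 4


def stage_rng(seed: int, stage: int, extra: int = 0) -> np.random.Generator:
    """Generator for one pipeline stage, derived from ``seed`` by fixed offsets."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31),
                                                        spawn_key=(int(stage), int(extra))))


@dataclass(frozen=True)
class QtlSpec:
    """One simulated QTL: position, additive effect, per-environment multiplier.

    ``effect`` is in trait-SD units; a positive effect means the RM allele
    raises the trait.  ``env_multiplier`` maps environment names to values in
    {-1, 0, +1} (times an optional magnitude): 0 encodes presence/absence GxE,
    -1 encodes a sign change relative to the baseline.
    """

    chrom: str
    pos: int
    effect: float
    env_multiplier: Mapping[str, float]

    def multiplier(self, environment: str) -> float:
        try:
            return float(self.env_multiplier[environment])
        except KeyError:
            raise KeyError(f"unknown environment {environment!r} for QTL at "
                           f"{self.chrom}:{self.pos}") from None


@dataclass(frozen=True)
class CrossDesign:
    """Design of one simulated cross and its sorted-pool sequencing."""

    n_segregants: int
    qtls: tuple[QtlSpec, ...] = ()
    residual_sd: float = 1.0
    tail_fraction: float = 0.02
    mean_depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tail_fraction < 0.5):
            raise ValueError("tail_fraction must be in (0, 0.5)")
        if self.n_segregants < 2 / self.tail_fraction:
            raise ValueError("n_segregants must be >= 2 / tail_fraction")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def environments(self) -> tuple[str, ...]:
        envs: list[str] = []
        for q in self.qtls:
            for e in q.env_multiplier:
                if e not in envs:
                    envs.append(e)
        return tuple(envs)


def design_from_toml(path) -> tuple[GenomeMap, CrossDesign]:
    """Load a ``[genome]`` / ``[cross]`` / ``[[qtl]]`` TOML cross config."""
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    g = cfg.get("genome", {})
    from .genome import toy_genome, saccer3_genome

    if g.get("preset", "toy") == "sacCer3":
        genome = saccer3_genome(marker_spacing=int(g.get("marker_spacing", 640)),
                                bp_per_cM=float(g.get("bp_per_cM", 2200.0)))
    else:
        genome = toy_genome(lengths=g.get("lengths", (600_000, 450_000)),
                            marker_spacing=int(g.get("marker_spacing", 640)),
                            bp_per_cM=float(g.get("bp_per_cM", 2200.0)))
    c = cfg.get("cross", {})
    qtls = tuple(QtlSpec(q["chrom"], int(q["pos"]), float(q["effect"]),
                         dict(q.get("env_multiplier", {})))
                 for q in cfg.get("qtl", []))
    design = CrossDesign(n_segregants=int(c.get("n_segregants", 5000)),
                         qtls=qtls,
                         residual_sd=float(c.get("residual_sd", 1.0)),
                         tail_fraction=float(c.get("tail_fraction", 0.02)),
                         mean_depth=float(c.get("mean_depth", 100.0)),
                         seed=int(c.get("seed", 0)))
    return genome, design


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def haldane_r(d_morgans: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction at ``d`` Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def simulate_segregant_genotypes(genome: GenomeMap, n: int,
                                 seed: int | np.random.Generator) -> dict[str, np.ndarray]:
    """Simulate ``n`` haploid meiotic products over the marker map.

    Each segregant's parental phase at the left chromosome end is BY or RM
    with probability 1/2; crossovers follow a Poisson process along the
    chromosome (Haldane, no interference), so the phase at consecutive
    markers is a two-state Markov chain whose switch probability per
    inter-marker gap is Haldane's map function at the gap's genetic length.
    Markers inherit the phase of their interval; the marker-level chain is
    therefore exactly equal in law to the breakpoint construction.

    Returns a dict mapping chromosome name to an ``(n, n_markers)`` int8
    matrix with 0 = BY, 1 = RM.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        pos = genome.markers_of(chrom)  # raises on empty marker set
        m = pos.size
        geno = np.empty((n, m), dtype=np.int8)
        geno[:, 0] = rng.integers(0, 2, size=n, dtype=np.int8)
        if m > 1:
            gaps_bp = np.diff(pos).astype(float)
            r = np.asarray(haldane_r(gaps_bp / (genome.bp_per_cM * 100.0)))
            switches = rng.random((n, m - 1)) < r[None, :]
            # cumulative XOR of switch indicators gives the phase along the chain
            parity = np.cumsum(switches, axis=1, dtype=np.int64) & 1
            geno[:, 1:] = (geno[:, :1] ^ parity.astype(np.int8))
        out[chrom] = geno
    return out


def _nearest_marker_index(genome: GenomeMap, chrom: str, pos: int) -> int:
    markers = genome.markers_of(chrom)
    i = int(np.searchsorted(markers, pos))
    if i == 0:
        return 0
    if i == markers.size:
        return markers.size - 1
    return i if (markers[i] - pos) < (pos - markers[i - 1]) else i - 1


# ---------------------------------------------------------------------------
# Trait and selection
# ---------------------------------------------------------------------------

def simulate_trait(genotypes: Mapping[str, np.ndarray], design: CrossDesign,
                   environment: str, genome: GenomeMap,
                   seed: int | np.random.Generator) -> np.ndarray:
    """Additive trait in one environment.

    ``trait_i = sum_q effect_q * mult_q(env) * s_iq + eps_i`` with allele score
    ``s = +1/2`` for RM and ``-1/2`` for BY at the marker nearest each QTL, and
    ``eps ~ Normal(0, residual_sd^2)``.  The trait is UPS activity: a positive
    effect times the RM genotype raises it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = next(iter(genotypes.values())).shape[0] if genotypes else design.n_segregants
    trait = rng.normal(0.0, design.residual_sd, size=n)
    for q in design.qtls:
        mult = q.multiplier(environment)  # raises on unknown environment
        if mult == 0.0:
            continue
        if q.chrom not in genotypes:
            raise ValueError(f"QTL chromosome {q.chrom} missing from genotypes")
        j = _nearest_marker_index(genome, q.chrom, q.pos)
        s = genotypes[q.chrom][:, j].astype(float) - 0.5
        trait += q.effect * mult * s
    return trait


def select_tails(trait: np.ndarray, tail_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the high and low phenotypic tails.

    Pool size is ``ceil(tail_fraction * n)`` (so tiny panels never yield empty
    pools).  Ties are resolved deterministically by a stable ascending sort:
    the low pool is the first k entries, the high pool the last k, each
    reported in index order.  The pools are disjoint whenever ``2k <= n``.
    """
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if not (0 < tail_fraction < 0.5):
        raise ValueError("tail_fraction must be in (0, 0.5)")
    k = math.ceil(tail_fraction * n)
    if 2 * k > n:
        raise ValueError("tails overlap: tail_fraction too large for n")
    order = np.argsort(trait, kind="stable")
    low = np.sort(order[:k])
    high = np.sort(order[-k:])
    return high, low


# ---------------------------------------------------------------------------
# Pooled sequencing
# ---------------------------------------------------------------------------

def simulate_read_counts(genotypes: Mapping[str, np.ndarray],
                         high: np.ndarray, low: np.ndarray,
                         genome: GenomeMap, mean_depth: float,
                         seed: int | np.random.Generator) -> pd.DataFrame:
    """Pooled sequencing of the two sorted pools.

    Per marker and pool, depth is Poisson(``mean_depth``); the RM read count
    is Binomial(depth, true pool RM frequency); BY reads make up the rest.
    Zero-depth markers are permitted (handled by the variant filter).

    Returns an allele-count track: columns ``chrom, pos, high_BY, high_RM,
    low_BY, low_RM``.
    """
    if len(high) == 0 or len(low) == 0:
        raise ValueError("pools must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for chrom in genome.chrom_names:
        geno = genotypes[chrom]
        pos = genome.markers_of(chrom)
        rec: dict[str, np.ndarray] = {"chrom": np.repeat(chrom, pos.size), "pos": pos}
        for label, members in (("high", high), ("low", low)):
            f = geno[members].mean(axis=0)
            depth = rng.poisson(mean_depth, size=pos.size)
            rm = rng.binomial(depth, f)
            rec[f"{label}_BY"] = depth - rm
            rec[f"{label}_RM"] = rm
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cytometry events
# ---------------------------------------------------------------------------

def simulate_cytometry_events(activity: float, gfp_level: float, n_events: int,
                              drift_slope: float = 0.0, noise_sd: float = 0.25,
                              fsc_scale: float = 100.0, fsc_sd: float = 0.1,
                              low_nitrogen: bool = False, duration_s: float = 60.0,
                              seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-cell events for one replicate sample of a two-color timer reporter.

    Events carry acquisition time (uniform over the sample window), log-normal
    forward/side scatter around a strain size parameter, log-normal GFP around
    the configured expression level, and RFP such that
    ``-log2(rfp/gfp) = activity + drift_slope * time + noise``.  A low-nitrogen
    sample doubles the FSC distribution into two modes (incompletely budded
    cells), the upper mode at twice the size parameter.
    """
    if n_events < 100:
        raise ValueError("n_events must be >= 100")
    if gfp_level <= 0:
        raise ValueError("gfp_level must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = rng.uniform(0.0, duration_s, size=n_events)
    t.sort()
    scale = np.full(n_events, float(fsc_scale))
    if low_nitrogen:
        upper = rng.random(n_events) < 0.5
        scale[upper] *= 2.0
    fsc = np.exp(rng.normal(np.log(scale), fsc_sd))
    ssc = np.exp(rng.normal(np.log(scale * 0.6), fsc_sd))
    gfp = np.exp(rng.normal(np.log(gfp_level), 0.15, size=n_events))
    ratio = activity + drift_slope * t
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, size=n_events)
    rfp = gfp * np.power(2.0, -ratio)
    return pd.DataFrame({"time_s": t, "fsc": fsc, "ssc": ssc, "gfp": gfp, "rfp": rfp})


# ---------------------------------------------------------------------------
# End-to-end cross
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPoolData:
    """One simulated cross: genotypes, traits, pools, counts, and truth."""

    genome: GenomeMap
    design: CrossDesign
    genotypes: dict[str, np.ndarray]
    traits: dict[str, np.ndarray] = field(default_factory=dict)
    pools: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def truth(self) -> pd.DataFrame:
        """Truth table of simulated QTLs, one row per QTL x environment."""
        rows = []
        for q in self.design.qtls:
            for env in self.design.environments:
                mult = q.env_multiplier.get(env, 0.0)
                rows.append({"chrom": q.chrom, "pos": q.pos, "effect": q.effect,
                             "environment": env, "multiplier": mult,
                             "signed_effect": q.effect * mult})
        return pd.DataFrame(rows)


def simulate_cross(genome: GenomeMap, design: CrossDesign,
                   seed: int | None = None,
                   environments: Sequence[str] | None = None) -> SimulatedPoolData:
    """Run the full generator: genotypes -> traits -> sorted pools -> counts.

    Per-stage seeds are derived from the master seed by fixed offsets, so each
    stage is independently reproducible.
    """
    master = design.seed if seed is None else seed
    envs = tuple(environments) if environments is not None else (design.environments or ("SC",))
    genotypes = simulate_segregant_genotypes(genome, design.n_segregants,
                                             stage_rng(master, STAGE_GENOTYPES))
    data = SimulatedPoolData(genome, design, genotypes)
    for i, env in enumerate(envs):
        trait = simulate_trait(genotypes, design, env, genome,
                               stage_rng(master, STAGE_TRAIT, i))
        high, low = select_tails(trait, design.tail_fraction)
        counts = simulate_read_counts(genotypes, high, low, genome, design.mean_depth,
                                      stage_rng(master, STAGE_COUNTS, i))
        data.traits[env] = trait
        data.pools[env] = (high, low)
        data.counts[env] = counts
    return data
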