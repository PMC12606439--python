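"""Tests of the synthetic cross generator: segregation, linkage, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bsa_gxe.genome import GenomeMap, toy_genome, evenly_spaced_markers
from bsa_gxe.simulate import (BY, RM, CrossDesign, QtlSpec, haldane_r,
                              select_tails, simulate_cross,
                              simulate_cytometry_events, simulate_read_counts,
                              simulate_segregant_genotypes, simulate_trait)


def flat_genome(length: int, spacing: int) -> GenomeMap:
    return GenomeMap((("chrI", length),),
                     {"chrI": evenly_spaced_markers(length, spacing)})


class TestGenotypes:
    def test_no_recombination_limit(self):
        # 22 bp chromosome = 0.01 cM: a segregant virtually never recombines
        genome = flat_genome(22, 2)
        geno = simulate_segregant_genotypes(genome, 5000, seed=0)["chrI"]
        mono = np.all(geno == geno[:, :1], axis=1).mean()
        assert mono >= 0.9999

    def test_haldane_recombinant_fraction(self):
        # closed-form Haldane oracle at the simulated inter-marker distance
        genome = flat_genome(4400, 2200)  # two markers 2,200 bp = 1 cM apart
        n = 10_000
        geno = simulate_segregant_genotypes(genome, n, seed=1)["chrI"]
        assert geno.shape[1] == 2
        obs = (geno[:, 0] != geno[:, 1]).mean()
        r = haldane_r(0.01)  # 1 cM = 0.01 Morgan -> r ~ 0.00990
        se = np.sqrt(r * (1 - r) / n)
        assert abs(obs - r) <= 3 * se

    def test_mendelian_segregation(self):
        genome = toy_genome((100_000,), marker_spacing=2_000)
        n = 10_000
        geno = simulate_segregant_genotypes(genome, n, seed=2)["chrI"]
        freq = geno.mean(axis=0)
        se = np.sqrt(0.25 / n)
        assert np.all(np.abs(freq - 0.5) <= 4 * se)
        # genome-wide mean within 4 SE as well
        assert abs(geno.mean() - 0.5) <= 4 * se

    @pytest.mark.parametrize("gap_bp", [1_100, 11_000, 110_000])
    def test_linkage_decay_matches_haldane(self, gap_bp):
        genome = flat_genome(2 * gap_bp, gap_bp)
        n = 10_000
        geno = simulate_segregant_genotypes(genome, n, seed=3)["chrI"]
        obs = (geno[:, 0] != geno[:, 1]).mean()
        r = haldane_r(gap_bp / 220_000.0)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(obs - r) <= 4 * se

    def test_errors(self):
        genome = flat_genome(1000, 100)
        with pytest.raises(ValueError, match="n must be"):
            simulate_segregant_genotypes(genome, 0, seed=0)
        empty = GenomeMap((("chrI", 1000),), {})
        with pytest.raises(ValueError, match="chrI"):
            simulate_segregant_genotypes(empty, 5, seed=0)

    def test_seed_determinism(self):
        genome = toy_genome((50_000,), marker_spacing=1_000)
        a = simulate_segregant_genotypes(genome, 50, seed=7)["chrI"]
        b = simulate_segregant_genotypes(genome, 50, seed=7)["chrI"]
        assert np.array_equal(a, b)


class TestTrait:
    genome = toy_genome((200_000,), marker_spacing=1_000)

    def design(self, qtls=()):
        return CrossDesign(n_segregants=5_000, qtls=tuple(qtls), seed=0)

    def test_null_trait_variance(self):
        d = self.design()
        geno = simulate_segregant_genotypes(self.genome, d.n_segregants, seed=4)
        trait = simulate_trait(geno, d, "SC", self.genome, seed=5)
        assert trait.var() == pytest.approx(1.0, rel=0.10)

    def test_zero_multiplier_identical_in_law(self):
        # with multiplier 0 the QTL contributes nothing: same noise stream
        # gives the exact same trait vector as the no-QTL design
        geno = simulate_segregant_genotypes(self.genome, 500, seed=6)
        q = QtlSpec("chrI", 100_000, 1.0, {"SC": 1.0, "E": 0.0})
        with_q = simulate_trait(geno, self.design([q]), "E", self.genome, seed=9)
        without = simulate_trait(geno, self.design(), "E", self.genome, seed=9)
        assert np.array_equal(with_q, without)

    def test_variance_explained(self):
        # allele score +-1/2 has variance 1/4; h2 = 0.25 / (0.25 + 1) = 0.2
        q = QtlSpec("chrI", 100_000, 1.0, {"SC": 1.0})
        d = self.design([q])
        geno = simulate_segregant_genotypes(self.genome, d.n_segregants, seed=10)
        trait = simulate_trait(geno, d, "SC", self.genome, seed=11)
        j = np.searchsorted(self.genome.markers_of("chrI"), 100_000)
        genetic = 1.0 * (geno["chrI"][:, j] - 0.5)
        r2 = genetic.var() / trait.var()
        assert r2 == pytest.approx(0.2, abs=0.03)

    def test_unknown_environment(self):
        q = QtlSpec("chrI", 100_000, 1.0, {"SC": 1.0})
        geno = simulate_segregant_genotypes(self.genome, 100, seed=0)
        with pytest.raises(KeyError, match="unknown environment"):
            simulate_trait(geno, self.design([q]), "nope", self.genome, seed=0)


class TestSelectTails:
    def test_extremes_of_a_ramp(self):
        trait = np.arange(1.0, 101.0)
        high, low = select_tails(trait, 0.02)
        assert set(high) == {98, 99}   # values 99, 100
        assert set(low) == {0, 1}      # values 1, 2

    def test_tie_rule_deterministic_and_disjoint(self):
        trait = np.zeros(50)
        high, low = select_tails(trait, 0.1)
        assert len(high) == len(low) == 5
        assert set(high).isdisjoint(low)
        h2, l2 = select_tails(trait, 0.1)
        assert np.array_equal(high, h2) and np.array_equal(low, l2)

    def test_pool_sizes(self):
        high, low = select_tails(np.random.default_rng(0).normal(size=1000), 0.02)
        assert len(high) == len(low) == 20

    def test_overlap_error(self):
        with pytest.raises(ValueError):
            select_tails(np.arange(10.0), 0.6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=10, max_size=200),
           st.floats(0.01, 0.4))
    def test_tail_properties(self, values, frac):
        trait = np.asarray(values)
        k = int(np.ceil(frac * trait.size))
        if 2 * k > trait.size:
            return
        high, low = select_tails(trait, frac)
        assert len(high) == len(low) == k
        assert set(high).isdisjoint(low)
        assert trait[high].min() >= trait[low].max()


class TestReadCounts:
    genome = toy_genome((50_000,), marker_spacing=1_000)

    def test_fixed_pool_has_no_by_reads(self):
        geno = {"chrI": np.ones((20, self.genome.n_markers), dtype=np.int8)}
        track = simulate_read_counts(geno, np.arange(10), np.arange(10, 20),
                                     self.genome, 30.0, seed=0)
        assert (track["high_BY"] == 0).all() and (track["low_BY"] == 0).all()

    def test_balanced_pool_mean_fraction(self):
        rng = np.random.default_rng(1)
        geno = {"chrI": rng.integers(0, 2, size=(200, self.genome.n_markers)).astype(np.int8)}
        track = simulate_read_counts(geno, np.arange(100), np.arange(100, 200),
                                     self.genome, 100.0, seed=2)
        frac = track["high_RM"] / (track["high_RM"] + track["high_BY"])
        m = self.genome.n_markers
        se = np.sqrt(0.25 / (100 * m)) + np.sqrt(0.25 / (200 * m))
        assert abs(frac.mean() - 0.5) <= 5 * se + 0.02

    def test_empty_pool_error(self):
        geno = {"chrI": np.ones((5, self.genome.n_markers), dtype=np.int8)}
        with pytest.raises(ValueError):
            simulate_read_counts(geno, np.array([], dtype=int), np.arange(5),
                                 self.genome, 10.0, seed=0)


class TestCytometryEvents:
    def test_noiseless_ratio_is_activity(self):
        ev = simulate_cytometry_events(activity=1.5, gfp_level=1000, n_events=200,
                                       drift_slope=0.0, noise_sd=0.0, seed=0)
        ratio = -np.log2(ev["rfp"] / ev["gfp"])
        assert np.allclose(ratio, 1.5, atol=1e-9)

    def test_low_nitrogen_doubles_fsc(self):
        ev = simulate_cytometry_events(activity=0, gfp_level=1000, n_events=20_000,
                                       low_nitrogen=True, seed=1)
        # two lognormal modes around 100 and 200
        logf = np.log(ev["fsc"])
        assert np.log(130) < logf.mean() < np.log(160)
        assert logf.std() > 0.3  # far wider than the single-mode sd of 0.1

    def test_event_validation(self):
        with pytest.raises(ValueError):
            simulate_cytometry_events(0.0, 1000, n_events=50)
        with pytest.raises(ValueError):
            simulate_cytometry_events(0.0, 0.0, n_events=200)


class TestCrossDesign:
    def test_invariants(self):
        with pytest.raises(ValueError):
            CrossDesign(n_segregants=10, tail_fraction=0.02)  # n < 2/f
        with pytest.raises(ValueError):
            CrossDesign(n_segregants=100, tail_fraction=0.6)
        with pytest.raises(ValueError):
            CrossDesign(n_segregants=100, residual_sd=0.0)

    def test_simulate_cross_round_trip(self):
        genome = toy_genome((60_000,), marker_spacing=2_000)
        q = QtlSpec("chrI", 30_000, 1.0, {"SC": 1.0, "E": -1.0})
        design = CrossDesign(n_segregants=200, qtls=(q,), mean_depth=20, seed=3)
        data = simulate_cross(genome, design, seed=3)
        assert set(data.counts) == {"SC", "E"}
        high, low = data.pools["SC"]
        assert len(high) == len(low) == 4  # ceil(0.02 * 200)
        truth = data.truth
        assert set(truth["environment"]) == {"SC", "E"}
        assert (truth.loc[truth.environment == "E", "multiplier"] == -1.0).all()
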