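"""Tests of variant filtering, binning, the hidden-state model, and calling.

The forward-backward recursion is pinned by an exhaustive path-enumeration
oracle on small chains, and the contrast LOD by direct evaluation on the
enumerated posteriors.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bsa_gxe.genome import toy_genome
from bsa_gxe.pool_mapping import (HmmParams, QtlRecord, bin_counts, call_qtls,
                                  contrast_lod, default_grid, drift_kernel,
                                  effective_counts, filter_variants, map_track,
                                  pool_posteriors, transition_matrix,
                                  _emissions)


def make_track(pos, h_by, h_rm, l_by, l_rm, chrom="chrI"):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "high_BY": h_by,
                         "high_RM": h_rm, "low_BY": l_by, "low_RM": l_rm})


class TestFilterVariants:
    def test_extreme_frequency_removed(self):
        track = make_track([100, 200, 300],
                           h_by=[5, 50, 50], h_rm=[95, 50, 50],
                           l_by=[50, 50, 50], l_rm=[50, 50, 50])
        out, log = filter_variants(track)
        assert list(out["pos"]) == [200, 300]
        assert log["n_extreme_af"] == 1

    def test_boundary_is_retained(self):
        # frequency exactly 0.1: strict inequality keeps the marker
        track = make_track([100], h_by=[90], h_rm=[10], l_by=[50], l_rm=[50])
        out, _ = filter_variants(track)
        assert len(out) == 1

    def test_zero_depth_removed(self):
        track = make_track([100, 200], h_by=[0, 10], h_rm=[0, 10],
                           l_by=[10, 10], l_rm=[10, 10])
        out, log = filter_variants(track)
        assert list(out["pos"]) == [200]
        assert log["n_zero_depth"] == 1

    def test_pooled_filter_option(self):
        # 0.95 in the high pool but 0.5 pooled: retained under pooled filtering
        track = make_track([100], h_by=[5], h_rm=[95], l_by=[95], l_rm=[5])
        params = HmmParams(per_pool_filter=False)
        out, _ = filter_variants(track, params)
        assert len(out) == 1
        out2, _ = filter_variants(track)
        assert len(out2) == 0


class TestBinCounts:
    def test_bin_assignment(self):
        centers, by, rm = bin_counts(np.array([50, 150]), np.array([3, 4]),
                                     np.array([1, 2]), 100, 200)
        assert by.tolist() == [3.0, 4.0]
        assert rm.tolist() == [1.0, 2.0]

    def test_position_100_goes_to_bin_0(self):
        _, by, _ = bin_counts(np.array([100]), np.array([7]), np.array([0]),
                              100, 200)
        assert by.tolist() == [7.0, 0.0]

    def test_counts_sum_within_bin_and_empty_bins_kept(self):
        centers, by, rm = bin_counts(np.array([10, 20, 350]),
                                     np.array([1, 2, 5]), np.array([3, 4, 6]),
                                     100, 400)
        assert len(centers) == 4
        assert by.tolist() == [3.0, 0.0, 0.0, 5.0]
        assert rm.tolist() == [7.0, 0.0, 0.0, 6.0]


class TestEffectiveCounts:
    def test_low_depth_barely_shrunk(self):
        by, rm = effective_counts(5.0, 5.0, 1000.0)
        assert by + rm == pytest.approx(10 * 1000 / 1010)  # d_eff ~ 9.90
        assert by == pytest.approx(5 * 1000 / 1010)

    def test_depth_equal_to_pool_size_halved(self):
        by, rm = effective_counts(400.0, 600.0, 1000.0)
        assert by + rm == pytest.approx(500.0)
        assert rm == pytest.approx(300.0)

    def test_infinite_pool_limit(self):
        by, rm = effective_counts(12.0, 34.0, 1e12)
        assert by == pytest.approx(12.0, rel=1e-9)
        assert rm == pytest.approx(34.0, rel=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0, 1e4), st.floats(0, 1e4), st.floats(1, 1e6))
    def test_shrinkage_properties(self, by, rm, N):
        b, r = effective_counts(by, rm, N)
        d = by + rm
        assert b + r <= min(d, N) + 1e-6
        if d > 0 and b + r > 0:
            # allele proportions are preserved by the shrinkage
            assert b / (b + r) == pytest.approx(by / d, rel=1e-9, abs=1e-12)


def brute_force_posteriors(by_eff, rm_eff, params):
    """Exhaustive path enumeration over the grid (oracle)."""
    g = params.grid
    G = g.size
    e = _emissions(np.asarray(by_eff, float), np.asarray(rm_eff, float), g)
    T = transition_matrix(params)
    nb = len(by_eff)
    post = np.zeros((nb, G))
    total = 0.0
    for path in itertools.product(range(G), repeat=nb):
        p = (1.0 / G) * e[0, path[0]]
        for t in range(1, nb):
            p *= T[path[t - 1], path[t]] * e[t, path[t]]
        total += p
        for t in range(nb):
            post[t, path[t]] += p
    return post / total


class TestForwardBackward:
    small = HmmParams(grid=default_grid(5), bin_bp=1000, effective_pool_size=50.0)

    def test_single_bin_posterior_mode(self):
        res = pool_posteriors([2.0], [8.0], HmmParams())
        g = HmmParams().grid
        mode = g[np.argmax(res.posterior[0])]
        assert mode == pytest.approx(0.8, abs=0.011)
        # single bin: posterior equals the normalized emission directly
        direct = g ** 8 * (1 - g) ** 2
        eff_by, eff_rm = effective_counts(2.0, 8.0, 1000.0)
        direct = g ** eff_rm * (1 - g) ** eff_by
        direct /= direct.sum()
        assert np.allclose(res.posterior[0], direct, atol=1e-12)

    def test_zero_counts_posterior_is_uniform(self):
        res = pool_posteriors([0.0] * 6, [0.0] * 6, self.small)
        assert np.allclose(res.posterior, 1.0 / 5, atol=1e-12)

    @pytest.mark.parametrize("nb,grid_n", [(3, 5), (4, 7)])
    def test_matches_path_enumeration(self, nb, grid_n):
        rng = np.random.default_rng(nb * 10 + grid_n)
        params = HmmParams(grid=default_grid(grid_n), bin_bp=1000,
                           effective_pool_size=50.0)
        by = rng.integers(0, 12, size=nb).astype(float)
        rm = rng.integers(0, 12, size=nb).astype(float)
        by_eff, rm_eff = effective_counts(by, rm, params.effective_pool_size)
        expected = brute_force_posteriors(by_eff, rm_eff, params)
        got = pool_posteriors(by, rm, params).posterior
        assert np.max(np.abs(np.log(got) - np.log(expected))) < 1e-9

    def test_empty_chromosome_error(self):
        with pytest.raises(ValueError):
            pool_posteriors([], [], self.small)


class TestContrastLod:
    def test_zero_counts_lod_exactly_zero(self):
        params = HmmParams(grid=default_grid(10), bin_bp=1000)
        h = pool_posteriors([0.0] * 4, [0.0] * 4, params)
        lod = contrast_lod(h, h, params)
        assert np.all(np.abs(lod) < 1e-12)  # zero up to float rounding

    def test_identical_counts_near_neutral(self):
        params = HmmParams(grid=default_grid(20), bin_bp=1000,
                           effective_pool_size=100.0)
        h = pool_posteriors([10.0, 12.0, 8.0], [10.0, 9.0, 12.0], params)
        lod = contrast_lod(h, h, params)
        assert np.all(lod <= 0.5)

    def test_opposed_pools_exceed_threshold(self):
        params = HmmParams()  # default fine grid, N = 1000
        h = pool_posteriors([10.0], [90.0], params)
        l = pool_posteriors([90.0], [10.0], params)
        assert contrast_lod(h, l, params)[0] > 4.5

    def test_pool_swap_symmetry(self):
        params = HmmParams(grid=default_grid(15), bin_bp=1000,
                           effective_pool_size=100.0)
        h = pool_posteriors([3.0, 9.0], [9.0, 2.0], params)
        l = pool_posteriors([8.0, 4.0], [4.0, 9.0], params)
        assert np.allclose(contrast_lod(h, l, params),
                           contrast_lod(l, h, params), atol=1e-12)

    def test_matches_direct_evaluation_on_enumerated_posteriors(self):
        rng = np.random.default_rng(42)
        params = HmmParams(grid=default_grid(7), bin_bp=1000,
                           effective_pool_size=50.0)
        counts = {p: (rng.integers(0, 15, 3).astype(float),
                      rng.integers(0, 15, 3).astype(float)) for p in "hl"}
        posts = {}
        for p, (by, rm) in counts.items():
            by_e, rm_e = effective_counts(by, rm, params.effective_pool_size)
            posts[p] = brute_force_posteriors(by_e, rm_e, params)
        K = drift_kernel(params)
        a_h = posts["h"] @ K
        a_l = posts["l"] @ K
        a_h /= a_h.sum(axis=1, keepdims=True)
        a_l /= a_l.sum(axis=1, keepdims=True)
        expected = -np.log10(7 * np.einsum("ij,ij->i", a_h, a_l))
        h = pool_posteriors(*counts["h"][::1], params)
        lod = contrast_lod(pool_posteriors(counts["h"][0], counts["h"][1], params),
                           pool_posteriors(counts["l"][0], counts["l"][1], params),
                           params)
        assert np.max(np.abs(lod - expected)) < 1e-9

    def test_count_scaling_never_increases_peak_lod(self):
        rng = np.random.default_rng(7)
        params = HmmParams(grid=default_grid(25), bin_bp=1000,
                           effective_pool_size=100.0)
        for _ in range(5):
            h_by = rng.integers(5, 40, 6).astype(float)
            h_rm = rng.integers(5, 40, 6).astype(float)
            l_by, l_rm = h_rm.copy(), h_by.copy()
            full = contrast_lod(pool_posteriors(h_by, h_rm, params),
                                pool_posteriors(l_by, l_rm, params), params).max()
            k = 0.4
            scaled = contrast_lod(pool_posteriors(h_by * k, h_rm * k, params),
                                  pool_posteriors(l_by * k, l_rm * k, params),
                                  params).max()
            assert scaled <= full + 1e-9


class TestCallQtls:
    def triangle(self):
        bins = np.arange(101)
        centers = (bins + 0.5) * 100 + 0.5
        lod = 6.0 - 0.1 * np.abs(bins - 50)
        daf = np.full(101, 0.3)
        return centers, lod, daf

    def test_triangular_peak_run_and_ci(self):
        centers, lod, daf = self.triangle()
        qtls = call_qtls("chrI", centers, lod, daf, threshold=4.5)
        assert len(qtls) == 1
        q = qtls[0]
        assert q.peak == centers[50]
        assert q.lod == 6.0
        # CI: lod >= 4.0 covers bins 30..70
        assert q.ci_left == centers[30]
        assert q.ci_right == centers[70]
        assert q.sign == "+"

    def test_flat_zero_no_calls(self):
        centers, lod, daf = self.triangle()
        assert call_qtls("chrI", centers, np.zeros_like(lod), daf) == []

    def test_two_runs_two_records(self):
        centers = (np.arange(40) + 0.5) * 100
        lod = np.zeros(40)
        lod[5:10] = 5.0
        lod[25:31] = 6.0
        daf = np.where(np.arange(40) < 20, 0.2, -0.2)
        qtls = call_qtls("chrI", centers, lod, daf, threshold=4.5)
        assert len(qtls) == 2
        assert qtls[0].sign == "+" and qtls[1].sign == "-"

    def test_leftmost_tie_peak(self):
        centers = (np.arange(10) + 0.5) * 100
        lod = np.array([0, 5, 5, 5, 0, 0, 0, 0, 0, 0.0])
        qtls = call_qtls("chrI", centers, lod, np.ones(10))
        assert qtls[0].peak == centers[1]

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            QtlRecord("chrI", peak=5.0, ci_left=10.0, ci_right=20.0,
                      lod=5.0, daf=0.1, sign="+")


class TestMapTrack:
    def test_pool_swap_flips_daf_keeps_lod(self):
        genome = toy_genome((60_000,), marker_spacing=1_000)
        rng = np.random.default_rng(3)
        n = genome.n_markers
        pos = genome.markers_of("chrI")
        h_rm = rng.binomial(50, 0.8, n)
        l_rm = rng.binomial(50, 0.2, n)
        track = make_track(pos, 50 - h_rm, h_rm, 50 - l_rm, l_rm)
        swapped = track.rename(columns={"high_BY": "low_BY", "low_BY": "high_BY",
                                        "high_RM": "low_RM", "low_RM": "high_RM"})
        params = HmmParams(effective_pool_size=100.0)
        lod1, q1, _ = map_track(track, genome, params)
        lod2, q2, _ = map_track(swapped, genome, params)
        assert np.allclose(lod1["lod"], lod2["lod"], atol=1e-9)
        assert np.allclose(lod1["daf"], -lod2["daf"], atol=1e-9)

    def test_constant_offset_tracks(self):
        # noiseless 0.7 vs 0.3 gives a flat smoothed daf of 0.4
        genome = toy_genome((30_000,), marker_spacing=1_000)
        pos = genome.markers_of("chrI")
        n = len(pos)
        track = make_track(pos, [30] * n, [70] * n, [70] * n, [30] * n)
        lod_df, _, _ = map_track(track, genome, HmmParams(effective_pool_size=200.0))
        assert np.allclose(lod_df["daf"], 0.4, atol=1e-6)
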