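"""Pooled-sequencing QTL mapping by a hidden-state allele-frequency contrast.

Given BY/RM read counts at markers in a high-activity and a low-activity
sorted pool, each pool's unknown RM allele frequency along a chromosome is
modeled as a hidden state on a discretized frequency grid:

* markers are summed into uniform physical bins (default 100 bp) so one
  transition step corresponds to a fixed genetic distance;
* the state evolves as a random walk whose per-bin variance is
  ``c * r * p * (1 - p)`` with ``r`` the recombination fraction per bin
  (Haldane's map function at ``bin_bp / (100 * bp_per_cM)`` Morgans), with a
  variance floor of one grid step squared to keep the kernel proper near the
  boundaries;
* read counts are first shrunk toward the finite sorted-pool information
  content via the effective pool size ``N`` (``d_eff = d N / (d + N)``), then
  enter a binomial-kernel emission with real-valued exponents, normalized
  over the grid;
* posteriors come from a scaled forward-backward pass.

The per-bin LOD contrasts a model in which both pools share one allele
frequency at the bin against a model in which their frequencies are free:
with normalized forward-backward state distributions ``A^H`` and ``A^L`` and
a uniform grid prior, ``LOD = -log10( G * sum_p A^H(p) A^L(p) )`` with ``G``
the grid size.  QTLs are maximal runs of bins with LOD at or above the
calling threshold (default 4.5); the reported interval is the 2-LOD drop
around the peak.  Effect sizes are the loess-smoothed RM allele-frequency
difference (high minus low) at the peak; a positive difference means the RM
allele raises activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeMap
from .simulate import haldane_r

TRACK_COLUMNS = ("chrom", "pos", "high_BY", "high_RM", "low_BY", "low_RM")


def default_grid(n: int = 100) -> np.ndarray:
    """Allele-frequency grid: ``n`` points centered on (0, 1), step ``1/n``."""
    step = 1.0 / n
    return np.linspace(step / 2.0, 1.0 - step / 2.0, n)


@dataclass(frozen=True)
class HmmParams:
    """Settings of the hidden-state allele-frequency model."""

    grid: np.ndarray = field(default_factory=default_grid)
    bin_bp: int = 100
    bp_per_cM: float = 2_200.0
    effective_pool_size: float = 1_000.0
    walk_scale: float = 1.0
    lod_threshold: float = 4.5
    daf_span: float = 0.1
    af_filter: tuple[float, float] = (0.1, 0.9)
    per_pool_filter: bool = True

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or g.size < 2:
            raise ValueError("grid must be a 1-D array with >= 2 points")
        if np.any(np.diff(g) <= 0) or g[0] <= 0 or g[-1] >= 1:
            raise ValueError("grid must be strictly increasing inside (0, 1)")
        if self.bin_bp <= 0 or self.bp_per_cM <= 0 or self.effective_pool_size <= 0:
            raise ValueError("bin_bp, bp_per_cM and effective_pool_size must be positive")
        object.__setattr__(self, "grid", g)

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def r_per_bin(self) -> float:
        """Recombination fraction spanned by one bin (Haldane)."""
        return float(haldane_r(self.bin_bp / (self.bp_per_cM * 100.0)))


# ---------------------------------------------------------------------------
# Variant filtering and binning
# ---------------------------------------------------------------------------

def filter_variants(track: pd.DataFrame,
                    params: HmmParams = HmmParams()) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop markers with extreme or undefined pool allele frequencies.

    A marker is removed if, in either pool (or in the pooled counts when
    ``per_pool_filter`` is false), the RM frequency is strictly below the
    lower or strictly above the upper filter bound (defaults 0.1 / 0.9), or
    if a pool has zero depth there.  Returns the filtered track and removal
    counts.
    """
    lo, hi = params.af_filter
    high_d = track["high_BY"] + track["high_RM"]
    low_d = track["low_BY"] + track["low_RM"]
    zero = (high_d == 0) | (low_d == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_high = track["high_RM"] / high_d
        f_low = track["low_RM"] / low_d
        if params.per_pool_filter:
            extreme = (f_high < lo) | (f_high > hi) | (f_low < lo) | (f_low > hi)
        else:
            f_all = (track["high_RM"] + track["low_RM"]) / (high_d + low_d)
            extreme = (f_all < lo) | (f_all > hi)
    extreme = extreme.fillna(False) & ~zero
    keep = ~(zero | extreme)
    log = {"n_input": int(len(track)), "n_zero_depth": int(zero.sum()),
           "n_extreme_af": int(extreme.sum()), "n_retained": int(keep.sum())}
    return track.loc[keep].reset_index(drop=True), log


def bin_counts(positions: np.ndarray, by: np.ndarray, rm: np.ndarray,
               bin_bp: int, chrom_length: int | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum marker counts into half-open physical bins.

    Bins are ``[k * bin_bp, (k + 1) * bin_bp)`` in 0-based coordinates
    (1-based positions are shifted by -1).  Empty bins are retained as
    zero-count bins so that the chain steps through uniform genetic distance.
    Returns (bin centers in 1-based bp, binned BY counts, binned RM counts).
    """
    positions = np.asarray(positions, dtype=np.int64)
    idx = (positions - 1) // bin_bp
    length = chrom_length if chrom_length is not None else (int(positions.max()) if positions.size else bin_bp)
    nb = max(math.ceil(length / bin_bp), (int(idx.max()) + 1) if idx.size else 1)
    by_b = np.bincount(idx, weights=np.asarray(by, dtype=float), minlength=nb)
    rm_b = np.bincount(idx, weights=np.asarray(rm, dtype=float), minlength=nb)
    centers = (np.arange(nb, dtype=float) + 0.5) * bin_bp + 0.5  # 1-based bp
    return centers, by_b, rm_b


def effective_counts(by: np.ndarray | float, rm: np.ndarray | float,
                     N: float) -> tuple[np.ndarray, np.ndarray]:
    """Shrink read counts toward the information content of a finite pool.

    With total depth ``d``, the effective depth is ``d N / (d + N)`` —
    sequencing reads resample a pool of only ``N`` segregant genomes, so depth
    beyond ``N`` adds little information.  Counts are scaled proportionally
    and become real-valued pseudo-counts; zero depth stays zero.
    """
    by = np.asarray(by, dtype=float)
    rm = np.asarray(rm, dtype=float)
    d = by + rm
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(d > 0, N / (d + N), 0.0)
    return by * scale, rm * scale


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------

def transition_matrix(params: HmmParams) -> np.ndarray:
    """Row-stochastic state-transition kernel for one bin step.

    Row ``i`` is a discretized Normal centered at grid point ``p_i`` with
    variance ``max(c * 2 r p_i (1 - p_i) / N, (step / 2)^2)``: the
    allele-frequency random walk of a finite pool of ``N`` genomes under a
    recombination fraction ``r`` per bin, floored at half a grid step so the
    discretized kernel stays proper (and honest) near the boundaries.
    """
    g = params.grid
    var = (params.walk_scale * 2.0 * params.r_per_bin * g * (1.0 - g)
           / params.effective_pool_size)
    var = np.maximum(var, (params.grid_step / 2.0) ** 2)
    diff2 = (g[None, :] - g[:, None]) ** 2
    T = np.exp(-diff2 / (2.0 * var[:, None]))
    # balance to doubly stochastic (Sinkhorn) so the uniform prior is the
    # chain's stationary distribution: a chromosome with no reads keeps the
    # exact uniform posterior and the contrast LOD is exactly zero there
    for _ in range(1000):
        T /= T.sum(axis=1, keepdims=True)
        T /= T.sum(axis=0, keepdims=True)
        if (np.abs(T.sum(axis=1) - 1.0).max() < 1e-14
                and np.abs(T.sum(axis=0) - 1.0).max() < 1e-14):
            break
    T /= T.sum(axis=1, keepdims=True)
    return T


def _emissions(by_eff: np.ndarray, rm_eff: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-bin emission distributions over the grid (rows normalized).

    Binomial-form kernel with real exponents: ``p^rm' (1-p)^by'``, normalized
    over the grid (the continuous-count generalization is proper after
    normalization).  Zero-count bins emit the uniform distribution.
    """
    logp = np.log(grid)
    log1p = np.log1p(-grid)
    loge = rm_eff[:, None] * logp[None, :] + by_eff[:, None] * log1p[None, :]
    loge -= loge.max(axis=1, keepdims=True)
    e = np.exp(loge)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class PoolPosterior:
    """Forward-backward output for one pool on one chromosome."""

    posterior: np.ndarray      # (n_bins, G) normalized state distributions
    log_evidence: float        # log of the chain's total (normalized-emission) evidence
    scale: np.ndarray          # per-bin scaling factors (evidence decomposition)
    mean_af: np.ndarray        # posterior mean RM frequency per bin

    @property
    def n_bins(self) -> int:
        return self.posterior.shape[0]


def pool_posteriors(by_binned: np.ndarray, rm_binned: np.ndarray,
                    params: HmmParams = HmmParams()) -> PoolPosterior:
    """Posterior state distributions for one pool along one chromosome.

    The initial distribution is uniform over the grid; messages are scaled
    per bin (equivalent to log-space arithmetic), and the per-bin scaling
    factors are returned as the evidence decomposition.
    """
    by_binned = np.asarray(by_binned, dtype=float)
    rm_binned = np.asarray(rm_binned, dtype=float)
    if by_binned.size == 0:
        raise ValueError("empty chromosome: no bins")
    g = params.grid
    G = g.size
    by_eff, rm_eff = effective_counts(by_binned, rm_binned, params.effective_pool_size)
    e = _emissions(by_eff, rm_eff, g)
    T = transition_matrix(params)
    nb = e.shape[0]

    alpha = np.empty((nb, G))
    scale = np.empty(nb)
    a = (1.0 / G) * e[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, nb):
        a = (alpha[t - 1] @ T) * e[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]

    beta = np.empty((nb, G))
    beta[-1] = 1.0
    for t in range(nb - 2, -1, -1):
        b = T @ (e[t + 1] * beta[t + 1])
        beta[t] = b / scale[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return PoolPosterior(posterior=post,
                         log_evidence=float(np.log(scale).sum()),
                         scale=scale,
                         mean_af=post @ g)


def drift_kernel(params: HmmParams) -> np.ndarray:
    """Finite-pool drift kernel applied to posteriors before the contrast.

    A sorted pool of ``N`` genomes carries its own sampling deviation around
    the selection-level allele frequency, with variance ``p (1 - p) / N``,
    locally constant along a linkage block.  The tied/free contrast concerns
    the selection-level frequency, so each pool's state posterior is convolved
    with this kernel before the overlap is taken; otherwise chance drift
    excursions in small pools are indistinguishable from selection signal.

    The kernel is column-normalized (each destination receives a normalized
    mixture over sources), which maps the uniform distribution to itself
    exactly, so zero-count chromosomes keep LOD identically zero.
    """
    g = params.grid
    var = np.maximum(g * (1.0 - g) / params.effective_pool_size, 1e-12)
    diff2 = (g[None, :] - g[:, None]) ** 2
    K = np.exp(-diff2 / (2.0 * var[:, None]))   # rows: source p, cols: destination
    return K / K.sum(axis=0, keepdims=True)


def contrast_lod(high: PoolPosterior, low: PoolPosterior,
                 params: HmmParams = HmmParams()) -> np.ndarray:
    """Per-bin LOD for "pools differ" against "pools tied at this bin".

    ``LOD_i = -log10( G * sum_p A_i^H(p) A_i^L(p) )`` — the log10 Bayes
    factor of frequencies-free versus frequencies-tied under the uniform grid
    prior, where ``A`` are the pools' forward-backward state distributions
    after convolution with the finite-pool drift kernel
    (:func:`drift_kernel`).  Zero everywhere both posteriors are uniform;
    large when the pools' selection-level frequencies separate beyond what
    finite-pool drift explains.
    """
    if high.n_bins != low.n_bins:
        raise ValueError("mismatched bin structure between pools")
    G = params.grid.size
    K = drift_kernel(params)
    a_h = high.posterior @ K
    a_l = low.posterior @ K
    a_h /= a_h.sum(axis=1, keepdims=True)
    a_l /= a_l.sum(axis=1, keepdims=True)
    overlap = np.einsum("ij,ij->i", a_h, a_l)
    return -np.log10(np.maximum(G * overlap, 1e-300))


# ---------------------------------------------------------------------------
# Smoothed allele-frequency difference
# ---------------------------------------------------------------------------

def smooth_daf(positions: np.ndarray, f_high: np.ndarray, f_low: np.ndarray,
               eval_at: np.ndarray, span: float = 0.1,
               weights_high: np.ndarray | None = None,
               weights_low: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Loess-smoothed per-pool RM frequencies and their difference.

    Raw per-marker frequencies are smoothed on position per pool (local
    linear loess, span as a fraction of the chromosome's markers) and
    evaluated at ``eval_at`` (bin centers).  With fewer than 10 markers the
    loess is unstable and a depth-weighted moving average is used instead;
    the returned flag reports the fallback.  Returns
    (smoothed high, smoothed low, daf, fallback_used).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size < 10:
        def wma(f: np.ndarray, w: np.ndarray | None) -> np.ndarray:
            w = np.ones_like(f) if w is None else np.asarray(w, dtype=float)
            k = min(5, f.size)
            sm = np.convolve(f * w, np.ones(k), mode="same") / \
                np.maximum(np.convolve(w, np.ones(k), mode="same"), 1e-12)
            return np.interp(eval_at, positions, sm)
        sh = wma(np.asarray(f_high, float), weights_high)
        sl = wma(np.asarray(f_low, float), weights_low)
        return sh, sl, sh - sl, True
    frac = max(span, min(10.0 / positions.size, 1.0))  # >= 10 markers per window
    sh = lowess(f_high, positions, frac=frac, it=1, xvals=eval_at)
    sl = lowess(f_low, positions, frac=frac, it=1, xvals=eval_at)
    return sh, sl, sh - sl, False


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

@dataclass
class QtlRecord:
    """One called locus with its 2-LOD support interval."""

    chrom: str
    peak: float
    ci_left: float
    ci_right: float
    lod: float
    daf: float
    sign: str
    replicate: str = ""
    reporter: str = ""
    environment: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_left <= self.peak <= self.ci_right):
            raise ValueError("CI must contain the peak")


def call_qtls(chrom: str, centers: np.ndarray, lod: np.ndarray, daf: np.ndarray,
              threshold: float = 4.5, chrom_length: int | None = None,
              replicate: str = "", reporter: str = "", environment: str = ""
              ) -> list[QtlRecord]:
    """Call QTLs as maximal runs of bins with LOD >= threshold.

    The peak is the leftmost argmax within the run; the confidence interval
    is the widest contiguous interval around the peak with LOD within 2 of
    the peak LOD (it may extend beyond the run), clipped at the chromosome
    ends.  The allele-frequency difference and its sign are taken at the
    peak bin.
    """
    lod = np.asarray(lod, dtype=float)
    daf = np.asarray(daf, dtype=float)
    centers = np.asarray(centers, dtype=float)
    above = lod >= threshold
    records: list[QtlRecord] = []
    i, n = 0, lod.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        run = slice(i, j + 1)
        peak_idx = i + int(np.argmax(lod[run]))  # argmax takes the leftmost tie
        drop = lod[peak_idx] - 2.0
        left = peak_idx
        while left - 1 >= 0 and lod[left - 1] >= drop:
            left -= 1
        right = peak_idx
        while right + 1 < n and lod[right + 1] >= drop:
            right += 1
        ci_left = centers[left]
        ci_right = centers[right]
        if chrom_length is not None:
            ci_left = max(ci_left, 1.0)
            ci_right = min(ci_right, float(chrom_length))
        d = float(daf[peak_idx])
        records.append(QtlRecord(chrom=chrom, peak=float(centers[peak_idx]),
                                 ci_left=float(ci_left), ci_right=float(ci_right),
                                 lod=float(lod[peak_idx]), daf=d,
                                 sign="+" if d >= 0 else "-",
                                 replicate=replicate, reporter=reporter,
                                 environment=environment))
        i = j + 1
    return records


# ---------------------------------------------------------------------------
# Whole-track driver
# ---------------------------------------------------------------------------

def map_track(track: pd.DataFrame, genome: GenomeMap,
              params: HmmParams = HmmParams(), *,
              replicate: str = "", reporter: str = "", environment: str = ""
              ) -> tuple[pd.DataFrame, list[QtlRecord], dict[str, int]]:
    """Filter, bin, score, smooth, and call QTLs for a whole count track.

    Returns a per-bin LOD table (columns chrom, bin_center, lod, af_high,
    af_low, daf), the called QTL records, and the variant-filter log.
    """
    filtered, log = filter_variants(track, params)
    lod_frames: list[pd.DataFrame] = []
    qtls: list[QtlRecord] = []
    for chrom in genome.chrom_names:
        sub = filtered[filtered["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        length = genome.length_of(chrom)
        centers, h_by, h_rm = bin_counts(pos, sub["high_BY"].to_numpy(),
                                         sub["high_RM"].to_numpy(),
                                         params.bin_bp, length)
        _, l_by, l_rm = bin_counts(pos, sub["low_BY"].to_numpy(),
                                   sub["low_RM"].to_numpy(),
                                   params.bin_bp, length)
        post_h = pool_posteriors(h_by, h_rm, params)
        post_l = pool_posteriors(l_by, l_rm, params)
        lod = contrast_lod(post_h, post_l, params)
        with np.errstate(invalid="ignore"):
            f_high = (sub["high_RM"] / (sub["high_BY"] + sub["high_RM"])).to_numpy()
            f_low = (sub["low_RM"] / (sub["low_BY"] + sub["low_RM"])).to_numpy()
        sh, sl, daf, _ = smooth_daf(pos, f_high, f_low, centers, span=params.daf_span)
        lod_frames.append(pd.DataFrame({
            "chrom": chrom, "bin_center": centers, "lod": lod,
            "af_high": sh, "af_low": sl, "daf": daf,
        }))
        qtls.extend(call_qtls(chrom, centers, lod, daf, params.lod_threshold,
                              chrom_length=length, replicate=replicate,
                              reporter=reporter, environment=environment))
    lod_df = pd.concat(lod_frames, ignore_index=True) if lod_frames else \
        pd.DataFrame(columns=["chrom", "bin_center", "lod", "af_high", "af_low", "daf"])
    return lod_df, qtls, log


def qtls_to_frame(qtls: Iterable[QtlRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(q) for q in qtls])
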