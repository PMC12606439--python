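# Methods

This note documents the models, parameter choices, and numerical decisions
behind `bsa_gxe`, and what the synthetic studies do and do not demonstrate.

## Synthetic cross generator

**Genotypes.** A segregant is one haploid meiotic product of a BY × RM
cross. The parental phase at the left end of each chromosome is BY or RM
with probability 1/2; crossovers follow a Poisson process with no
interference at 2,200 bp per centiMorgan, the genome-wide average for this
cross. Implementation simulates the phase only at marker positions: under a
no-interference model the marker-level phase is a two-state Markov chain
whose switch probability per inter-marker gap is Haldane's map function
r = (1 − e^(−2d))/2 at the gap's genetic length d, exactly the law of the
breakpoint construction restricted to the positions the pipeline observes.
The default marker panel places one marker per 640 bp, reproducing the
density of the ~18.9k genome-wide SNP panel (12.07 Mb / 640 bp).

**Trait and selection.** The trait (UPS activity) is additive:
`trait = Σ_q effect_q · mult_q(env) · s_q + ε`, with allele score s = ±1/2
at the marker nearest each QTL, residual ε ~ N(0, σ²) with σ = 1 by default.
Per-environment multipliers in {−1, 0, +1} construct sign-change,
presence/absence, and shared loci directly, so classification truth is known
by construction. Selection takes the ⌈f·n⌉ largest and smallest trait values
(f = 0.02 by default, the sorted-tail fraction; the ceiling guarantees
non-empty pools in small test panels). Ties are resolved by a stable
ascending sort — low pool from the bottom, high pool from the top — which is
deterministic, index-ordered within each pool, and keeps the pools disjoint.
Selection acts on the segregant's trait directly; single-cell measurement
noise during sorting can be emulated by adding a noise term to the trait
before selection, but no claim is made about the realized selection
differential of a real sorter.

**Sequencing.** Per marker and pool, depth ~ Poisson(mean_depth), RM reads ~
Binomial(depth, pool RM frequency). No sequencing-error model beyond
binomial sampling; zero-depth markers are legal and removed by the variant
filter.

**Cytometry events.** Events carry a uniform acquisition time, log-normal
scatter around a strain size parameter (two modes at 1× and 2× for
low-nitrogen samples, emulating incomplete budding), log-normal GFP around
the reporter's expression level, and RFP = GFP · 2^−(activity + drift·t + noise).
A linear drift slope injects the acquisition-time artifact the loess
correction is designed to remove.

**Seeds.** Every stochastic operation takes an explicit seed or Generator; a
pipeline run derives per-stage streams from one master seed by fixed offsets
(`simulate.stage_rng`), so stages are independently reproducible.

## Cytometry processing

Order of operations per replicate: lower-FSC-mode selection (only for
flagged low-nitrogen samples), ±10% median-FSC gate, drift correction,
summary. The mode split estimates the log-FSC density with a Gaussian kernel
(Silverman bandwidth, 512-point grid) and cuts at the deepest minimum
between the two highest maxima; "smaller peak" is read as lower FSC, which
matches the observation that the retained mode's median FSC resembles the
other samples'. The gate recomputes nothing: one pass, bounds from the input
median (midpoint convention). Exact idempotence would require a fixed-point
median and does not hold for skewed continuous samples; a second gate
removes at most a sliver (tested ≥ 97% retained, typically ≈ 99%).

Drift correction: raw = −log2(RFP/GFP) (events with non-positive
fluorescence are dropped and counted; fewer than 30 usable events is an
error); a local-linear loess of raw on time (span 0.75 by default — wide
enough to track acquisition drift, far too wide to absorb cell-level
variation) is subtracted, and the sample mean of raw is added back after
centering the residuals. The centering makes mean preservation exact rather
than approximate, which matters because downstream analyses compare
activities *between* samples — raw residuals (mean zero) would erase those
differences. The replicate's central value is the median of corrected
activity; the mean is recorded alongside.

The negative-control rule is deliberately group-wise: if any replicate of a
(reporter, environment) group has median GFP strictly below the reporter-free
control, the reporter is deemed unmeasurable in that environment and the
whole group is excluded. With the two proteasome-direct reporters
unmeasurable in nitrogen starvation, the surviving design yields 40
interaction tests and 80 per-strain t-tests, and the Bonferroni thresholds
0.00125 and 0.000625 fall out of the counting rather than being constants.

## Strain-level GxE model

Per reporter and environment pair (baseline SC vs E):
`activity ~ C(strain) * C(environment)` with a random intercept per
strain:replicate (the same transformant measured in both environments; a
switch covers the case of independent per-environment replicates). The
response is centered before fitting so results are exactly invariant to
constant shifts. REML fitting tries BFGS, then Powell, then L-BFGS — the
mixed-model likelihood for a 2×2×8 design is small but can be numerically
awkward. If the random-effect variance estimates to (numerically) zero or no
optimizer converges, the model falls back to fixed effects and flags it; the
fallback keeps replicate as a fixed blocking factor whenever the grouping is
non-trivial, because dropping the pairing would silently discard most of the
interaction test's power, and uses Type II sums of squares (identical to
Type I/III in the balanced case; documented for unbalanced fixtures).
Per-strain environment contrasts are Welch t-tests (variance pooling is not
assumed); environment effects are mean differences against the baseline,
computed per plate and averaged when a reporter is plate-paired so constant
plate offsets cancel.

Calibration (test suite and acceptance script): with zero interaction and
replicate and residual SDs of 0.3 each, the interaction test rejects at
5% ± 4% over 200 datasets; with an interaction of 3× the within-group SD
(3·√(0.3² + 0.3²) ≈ 1.27) and 8 replicates it clears the 0.00125 family
threshold in ≥ 95% of datasets.

## Pooled-sequencing QTL mapping

**Filtering and binning.** Markers with a pool RM frequency strictly below
0.1 or above 0.9 in either pool, or zero depth in a pool, are removed (the
per-pool rule is the default; a flag switches to pooled counts). Retained
counts are summed into half-open 100-bp bins in 0-based coordinates; empty
bins are kept so each transition step spans a fixed genetic distance,
r = Haldane(100 bp / 220,000 bp per Morgan) ≈ 4.5·10⁻⁴ per bin.

**Hidden state.** Each pool's RM frequency along a chromosome is a state on
a grid of 100 points (0.005…0.995). The transition from p is a discretized
Normal with variance `max(c · 2 r p (1 − p) / N, (step/2)²)` — the random
walk of an allele frequency in a finite pool of N genomes under
recombination, floored at half a grid step so the discretized kernel never
degenerates to the identity. The kernel is balanced to doubly stochastic
(Sinkhorn iteration), making the uniform prior stationary: a chromosome with
no reads keeps an exactly uniform posterior and an exactly zero LOD.
Emissions shrink the binned counts by the effective-depth transform
d_eff = d·N/(d+N) (reads resample only N genomes; depth beyond N adds little)
and use the binomial kernel p^rm′(1−p)^by′ with real exponents, normalized
over the grid. Messages are scaled per bin (equivalent to log-space
arithmetic); the per-bin scale factors are returned as the evidence
decomposition. Forward–backward is pinned by an exhaustive path-enumeration
oracle on chains up to 4 bins × 7 grid points (agreement to 10⁻⁹ in log
space, in tests and in the acceptance script).

**Contrast LOD.** At each bin, the normalized forward–backward distributions
A^H, A^L are first convolved with a finite-pool drift kernel of variance
p(1−p)/N. This is the load-bearing calibration choice: a sorted pool of N
genomes differs from the selection-level allele frequency by a locally
coherent sampling excursion of exactly that variance, and the tied/free
contrast concerns the selection-level frequency — without the convolution,
chance drift excursions in small pools are indistinguishable from signal
(measured on null crosses with pools of 40: 4–7 spurious LOD ≥ 4.5 calls per
genome without it, zero with it). The kernel is column-normalized so the
uniform distribution maps to itself and zero-count LOD stays exactly zero.
Then `LOD = −log10(G · Σ_p Ã^H Ã^L)` — the log10 Bayes factor of
"frequencies free" versus "frequencies tied at this bin" under the uniform
grid prior. N defaults to 1,000, the published effective pool size
appropriate for real sorted pools of ≥ 20,000 cells; the synthetic studies
set N to the simulated tail-pool size (⌈f·n⌉), which is what the parameter
means.

**ΔAF and calling.** Effect sizes come from a separate loess smooth (span
0.1 of a chromosome, floored at 10 markers per window; a depth-weighted
moving average replaces it below 10 markers and is flagged) of the raw
per-marker pool frequencies, evaluated at bin centers; ΔAF = high − low, and
positive ΔAF means the RM allele raises activity. QTLs are maximal runs of
bins with LOD ≥ 4.5 (the threshold reported to give a 0.5% false-discovery
rate for this design); the peak is the leftmost argmax, and the confidence
interval is the contiguous region around the peak with LOD within 2 of the
peak, which may extend beyond the run and is clipped at chromosome ends.
All reported positions are 1-based bin centers.

## Reconciliation and GxE classification

Replicate reconciliation pairs QTLs greedily by increasing peak distance,
requiring the same chromosome, peaks within 100 kb, and the same ΔAF sign;
each record is used at most once (nearest peak wins on multi-way ties — the
tie-break is this package's choice), matched fields are averaged, and
unmatched records keep single-replicate support. Cross-study overlap uses
the same 100-kb peak rule against either prior replicate, with sign
concordance recorded separately, and the shared-versus-unique comparison is
a two-sided pooled t-test on LOD and |ΔAF| (flagged not-computable when a
group has fewer than two members).

Classification anchors on loci with both-replicate support in at least one
environment of a (SC, E) pair. If either replicate of the other environment
has a peak within 100 kb: sign change when the nearest such peak's sign
differs, otherwise no GxE (magnitude differences are deliberately not
classified — the sorted-pool design cannot detect them reliably). No peak
within 100 kb in either replicate: presence/absence. When both environments
carry a both-replicate locus within 100 kb, the pair is deduplicated to one
call (nearest-peak pairing); loci that are single-replicate in both
environments are not classified. Genome summaries tile chromosomes into
100-kb half-open bins (the 16 nuclear chromosomes give exactly 128), count
peaks per bin, rank-correlate QTL and GxE counts over bins with at least one
QTL (average ranks, t-approximation p), and test direction balance with an
exact two-sided binomial test (minimum-likelihood method).

## Study conditions and what the tests show

The calibration studies run on a two-chromosome genome (600 + 450 kb, one
marker per 640 bp — full-genome marker density at a fraction of the size,
chosen so ten replicated simulations complete in minutes on one core):

* **Null calibration:** 10 replicated null crosses (2,000 segregants, pools
  of 40, depth 50) yield zero both-replicate calls at LOD ≥ 4.5.
* **Recovery:** a single 0.75-SD QTL (5,000 segregants, pools of 100, depth
  100) is recovered as exactly one both-replicate locus within 150 kb of the
  truth with the correct sign in ≥ 9/10 seeds (observed 10/10, median peak
  error a few kb). Single-replicate tracks may carry LOD ≈ 4.5 satellites on
  the flanks of a true locus where linked signal rides on pool drift; these
  rarely replicate and are removed by reconciliation, which is why
  replicated support is the calling unit.
* **GxE categories:** constructed presence/absence, sign-change, and no-GxE
  loci at 0.75 SD receive their constructed category in ≥ 80% of cases
  (observed ≈ 97%).

What passing these studies does *not* show: the generator has no read-depth
heterogeneity beyond Poisson, no alignment or mapping-bias artifacts, no
marker-density gaps, no segregation distortion, and selection acts on the
trait without sorter noise. Real-data behavior near repetitive regions, at
extreme allele frequencies, or with uneven coverage is untested. The LOD
scale of this model is not numerically identical to the original pooled-
sequencing tool's output; the threshold 4.5 carries its published FDR
interpretation only by analogy.

## Known limitations

* The drift kernel treats pool excursions as independent between bins when
  computing the contrast, which is conservative at long range and slightly
  anti-conservative at very short range; the null study bounds the net
  effect at these conditions.
* The mixed model reports Wald z p-values (normal approximation); with 16
  groups the interaction type-I error runs a point or two above nominal at
  α = 0.05, within the tested band.
* FCS binary parsing is out of scope; event tables arrive as CSV/TSV.
* Coordinates are single-build; no liftover between genome versions.
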