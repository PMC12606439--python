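# bsa-gxe

Bulk-segregant QTL mapping and genotype-by-environment (GxE) classification
for ubiquitin-proteasome system (UPS) activity screens in yeast.

## The problem

UPS activity in single cells can be read out with tandem fluorescent protein
timers: a GFP–RFP fusion carrying a degradation signal (degron), whose
−log2(RFP/GFP) ratio is proportional to the construct's degradation rate
because the two fluorophores mature at different speeds. Crossing two yeast
strains (the lab strain BY and the vineyard isolate RM), sorting the 2%
highest- and lowest-activity segregants by FACS, and sequencing the sorted
pools maps quantitative trait loci (QTLs): genome regions where the pools'
allele frequencies separate. Comparing the loci found in a baseline medium
(SC) against other environments reveals GxE — loci present in one
environment but not another ("presence/absence") or with opposite allelic
direction ("sign change").

This package implements that computational chain end to end, together with a
synthetic cross generator so every stage can be exercised and calibrated
without any sequencing data:

1. **cytometry** — per-cell event tables → size gating (±10% of median FSC),
   lower-mode selection for bimodal low-nitrogen samples, loess correction of
   acquisition-time drift in −log2(RFP/GFP) ("UPS activity"), replicate
   summaries, and exclusion of reporter/environment groups whose GFP falls
   below the reporter-free control.
2. **strain_gxe** — `activity ~ strain × environment + (1|replicate)` mixed
   models per reporter, with a fixed-effects fallback, Bonferroni families
   derived from the design's own exclusion accounting (40 interaction tests
   → threshold 0.05/40 = 0.00125; 80 per-strain t-tests → 0.000625), and
   per-strain environment-effect deltas.
3. **pool_mapping** — per-variant BY/RM counts in the high/low pools →
   variant filter (allele frequency outside (0.1, 0.9) in a pool), 100-bp
   binning at 2,200 bp/cM, a discretized hidden-state random-walk model of
   each pool's allele frequency, a per-bin LOD contrasting "pools share one
   frequency" against "frequencies differ", loess-smoothed allele-frequency
   differences (ΔAF), and QTL calls at LOD ≥ 4.5 with 2-LOD support
   intervals.
4. **qtl_catalog** — replicate reconciliation (peaks within 100 kb, same ΔAF
   sign, fields averaged) and cross-study overlap with t-tests on LOD and
   |ΔAF|.
5. **gxe_classify** — presence/absence, sign-change, and no-GxE calls per
   locus and environment pair; 100-kb genome bins (the 16 nuclear
   chromosomes tile into exactly 128), Spearman correlation of QTL and GxE
   counts per bin, and an exact binomial test of allelic direction balance.
6. **simulate** — the generator: Haldane crossovers at 2,200 bp/cM, additive
   QTL effects with per-environment multipliers in {−1, 0, +1} (encoding
   sign-change and presence/absence GxE by construction), truncation
   selection of the 2% tails, Poisson/binomial pooled sequencing, and
   timer-reporter cytometry events with configurable drift.

The per-bin LOD is a posterior Bayes factor: with forward–backward state
distributions A^H, A^L over a frequency grid of G points (uniform prior),

    LOD_i = −log10( G · Σ_p Ã_i^H(p) · Ã_i^L(p) ),

where Ã are the posteriors convolved with a finite-pool drift kernel of
variance p(1−p)/N — a sorted pool of N genomes carries locally coherent
sampling excursions around the selection-level frequency, and the contrast
must not mistake them for signal. See `docs/methods.md` for the full model.

## Worked example

`analysis/` holds the numbered study drivers. `04_map_qtls.py` simulates a
replicated cross with three constructed 0.75-SD loci (presence/absence at
chrI:150k, sign change at chrI:480k, no GxE at chrII:220k; 5,000 segregants,
2% tails, depth 100) and maps every replicate and environment:

```
$ python analysis/04_map_qtls.py
model: grid 100 states, bin 100 bp, 2200.0 bp/cM, effective pool 100, LOD threshold 4.5
replicate r1 SC: 1621/1641 markers kept, 4 QTLs:
  chrI:148250 LOD 22.3 dAF +0.62 CI [142650, 158950]
  chrI:477950 LOD 19.8 dAF +0.60 CI [471250, 485450]
  chrII:225550 LOD 21.8 dAF +0.64 CI [222050, 230250]
  ...
replicate r2 E: 1641/1641 markers kept, 7 QTLs:
  chrI:477750 LOD 20.5 dAF -0.58 CI [473050, 482250]
  chrII:218550 LOD 23.5 dAF +0.65 CI [213450, 225350]
  ...
```

Each line is one called locus: peak position, LOD at the peak, the smoothed
RM allele-frequency difference between high and low pools (positive = the RM
allele raises UPS activity), and the 2-LOD confidence interval. The strong
loci sit within a few kb of the constructed positions; the sign-change locus
flips ΔAF between SC and E. Low-LOD (≈4.5) satellites from finite-pool drift
appear in single replicates and are removed by the replicate reconciliation
(`05_reconcile_replicates.py`); `06_classify_gxe.py` then recovers the three
constructed GxE categories:

```
$ python analysis/06_classify_gxe.py
 chrI     151000.5 presence_absence
 chrI     477750.5      sign_change
chrII     216350.5           no_gxe
...
direction balance: 5/7 loci RM-increasing, binomial p=0.453
```

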