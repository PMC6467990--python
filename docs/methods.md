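# Methods

## The model of priming

The analysis targets a three-way temporal structure over genes *g*, genotypes
(wild type, demethylase mutant) and stages (C0, C14, C14S1, C14S7):

* a **mark change** Δme2(g) = log₂(RPKM_mut/RPKM_WT) of H3K4me2 at the callus
  stage C14,
* a **concurrent expression change** Δexpr_C14(g), expected ≈ 0 for primed
  genes,
* a **lagged expression change** Δexpr_C14S1(g) after shoot induction,
  expected negative for primed genes (failed activation in the mutant).

A gene is *primed* when the first quantity is large while only the third, not
the second, responds. The pipeline operationalizes this as (a) the Pearson
correlation of Δme2 with Δexpr at each stage, (b) a paired Wilcoxon
signed-rank test comparing each mark-change group's expression ratios at C14
vs C14S1, and (c) a conjunctive gene-level selection (hyper-mark ∩ induced in
WT ∩ down in mutant at S1 ∩ TF-bound).

## Statistical primitives

**Paired count test.** Differential calls between two conditions measured in
paired replicates use, per replicate k with counts (a_k, b_k) and library
sizes (A_k, B_k): n_k = a_k + b_k, π_k = A_k/(A_k+B_k),
p_k = P(X ≥ a_k | Binomial(n_k, π_k)), z_k = Φ⁻¹(1−p_k) clamped to ±8, and
Z = Σ z_k/√K with two-sided p = 2Φ(−|Z|). Replicates with n_k = 0 carry no
evidence and are dropped; if all are empty, p = 1. The fold-change effect is
the ratio of pseudocounted replicate-mean RPM. The test is exact at small
counts, respects the paired design (any multiplicative per-replicate factor
common to both conditions cancels in the conditional binomial), and replaces
a negative-binomial empirical-Bayes caller; genome-scale gene counts from such
callers are therefore not expected to be reproduced exactly, but all
thresholds (FC > 1.25 / < 0.8, ratio > 1.5, q < 0.01) are kept.

**Multiple testing.** DEG and hyper-mark calls apply the thresholds to
Benjamini–Hochberg q-values at the published 0.01 cutoff; per-group lag-test
p-values are reported raw, matching how −log₁₀ p is usually displayed for a
handful of groups.

**Wilcoxon signed-rank.** Zero differences are dropped; |d| are midranked;
W⁺ is the positive-rank sum. For n ≤ 25 the two-sided p is exact over the 2ⁿ
sign-flip distribution, computed by shift-convolution on doubled midranks
(ties are conditioned on, so the enumeration remains exact). For n > 25 a
normal approximation with tie-corrected variance and continuity correction is
used; on tie-free samples of n = 20–25 it agrees with the exact p to < 0.02.

**Pseudocounts and ratios.** "Half-minimum" pseudocounting adds half of the
smallest strictly positive value of the whole matrix (recorded on the result
for audit) before any ratio; replicates are collapsed by arithmetic mean of
normalized values for ratios and display tables, while tests always consume
per-replicate counts. Row z-scores use the population (divisor-n) standard
deviation; constant rows map to zero.

## Binding caller

The genome is tiled with 500 bp windows at 250 bp step. For each window,
λ_local is the maximum of (i) the library-scaled control count in the window,
(ii) the scaled control count in a 10 kb centred span rescaled to window
size, and (iii) the genome-wide treatment rate; the window p-value is the
Poisson upper tail of the treatment count. Because windows count reads by
≥ 1 bp overlap, the expected count in a span of width w is proportional to
w + L (L = fragment length), so terms (ii) and (iii) are rescaled by
(w + L)/(span + L); rescaling by w/span alone would underestimate the local
expectation by ~1.5× at the defaults and leave the noisy window-level control
count alone to set λ. Windows are BH-adjusted genome-wide; windows at
q < 0.1 are merged when overlapping or book-ended (peak q = min member q) and
peaks are assigned to genes by ≥ 1 bp overlap with the genic region (body
± 2 kb) — the same span over which the TF is profiled. No summit refinement,
fragment-size estimation or duplicate filtering is attempted: downstream
analysis consumes only the gene-level bound set.

## Interval conventions

Coordinates are 0-based half-open throughout; GFF3 is converted on ingest.
Reads are resized to the 250 bp average fragment length by fixing the 5′ end
and extending (or truncating) toward the 3′ end; the operation is idempotent
and clamps at position 0 and at chromosome ends when lengths are known. A
read overlapping k genic regions counts once in each. Metagene profiles
rescale each gene body to 100 bins and each 2 kb flank to 50 bins (bin means
taken from the cumulative coverage with linear interpolation at fractional
edges, which also defines the behaviour for bodies shorter than the bin
grid); minus-strand genes are reversed so bins run 5′→3′.

## The synthetic-data generator

The generator emulates the deposited study design: 2 genotypes × 4 stages,
RNA in triplicate, mark ChIP (H3, H3K4me1/2/3, H3K27me3) in duplicate at
C0/C14/C14S1, one TF ChIP/control pair at C14. Defaults: 2000 genes
(1–3 kb bodies, ≥ 4 kb gaps so 2 kb flanks never merge, 5 chromosomes), 10%
primed, mutant me2 effect ×2 at C14 carried to C14S1, induction fold ×2 at
S1/S7 on 20% of genes, mutant attenuation ×0.5 on primed genes, 10%
repressed genes, 30% bound, 4× TF enrichment with 75% of signal reads in the
3′ body half, me1/me3 positive fractions 0.5 each, mean count 100 per gene.
Primed genes are drawn inside bound ∩ me1⁺me3⁺ ∩ induced (configurable),
mirroring where the demethylase's targets concentrate.

**Count model.** Counts are gamma–Poisson: each (gene, assay, replicate
index) draws a unit-mean gamma factor with variance `nb_dispersion` (default
0.05, i.e. a biological CV of ~22%) shared across genotypes and stages, and
counts are Poisson around baseline × condition multiplier × factor.
Marginally the counts are negative binomial at the configured dispersion;
within a replicate pair the factor cancels, which is precisely the situation
a paired test is designed for and what treating replicates as paired buys.
This is a deliberate idealization: in real data, pairing removes only the
shared part of the biological variation, so the paired binomial test is
better calibrated here than it would be on arbitrary designs.

**Depth model.** Library sizes are the per-assay expected baseline totals
(matched effective sequencing depth), so RPM/RPKM ratios are free of
composition renormalization. With column-sum library sizes, the injected
effects — 10–20% of a 2000-gene universe changing two-fold — would shift
every library total by 10–20% and push ~150 null genes below the FC < 0.8
line, an artifact that genome-scale data does not show at this magnitude
(and that normalization methods like TMM exist to remove; such methods are
out of scope here). Samples backed by emitted BED files instead record the
actual read count, keeping the sample sheet consistent with the files.

**TF tracks.** TF ChIP is a genome-uniform input-like background (50
reads/gene-equivalent per replicate) plus Poisson signal reads in bound-gene
bodies; the control is the background alone. TF tracks carry Poisson noise
only — the enrichment caller models technical sampling noise, and modelling
extra biological dispersion there would require a caller that estimates it,
which the windowed Poisson model deliberately does not. Emitted reads are
175 bp (pre-extension) so the 250 bp extension step is always exercised.

**Stage dynamics.** H3K4me2 gains a per-gene log-normal factor (mean ×1.5,
log-sd 0.5) during callus formation, shared between genotypes and maintained
through C14S1; me1/me3 gain milder factors (×1.2). The me2 spread is chosen
so genotype-vs-genotype scatters of stage deltas reproduce the high
correlations (r ≥ 0.95) that replicate scatters of real data show.

**What the generator does not model.** Sequence-level effects (mappability,
GC bias), duplicate reads, batch effects beyond the shared replicate factor,
TMM-style composition shifts, unannotated transcription, and
dispersion–mean trends. Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under its stated assumptions, not
robustness to every artifact of real sequencing data.

## Numerical and design choices

* Group boundaries Δ = 0 and Δ = 1 are assigned to the middle group
  (closed interval) for totality; with pseudocounted ratios they have
  measure zero.
* me-state positivity is strict (> 20 RPKM); exactly 20 is negative.
* Per-replicate normal scores are clamped to ±8 to keep arithmetic finite at
  p_k ∈ {0, 1}.
* λ values are floored at 10⁻¹² and windows with zero treatment count get
  p = 1 directly.
* The hyper-mark operation reports raw p and BH q per gene; set membership
  uses q, consistent with the DEG calls.
* Library size semantics (total mapped vs total counted reads) are taken
  from the sample sheet as given; the simulator documents its own choice
  above.
* The target intersection uses BH-adjusted calls on every leg and no
  expression floor.
* An optional per-gene H3-ratio normalization mode for the methylation
  tracks is not implemented; H3 is carried as its own assay and can be
  ratioed by callers explicitly if desired.
* All randomness flows from a single integer seed; identical configurations
  give byte-identical outputs, and the run manifest records SHA-256 checksums
  of every artifact.

## Problem sizes

Default analyses run at 2000 genes; calibration sweeps use 20 independent
seeds; the test suite's structural tests use 300-gene datasets. These sizes
give stable estimates of the recovery and calibration properties (KS
distances of ~0.01 on ~40 000 pooled null p-values) while keeping a full
pipeline run in seconds on one CPU.

## Known limitations

* The paired count test presumes the within-pair conditional-binomial
  structure; under unpaired overdispersion it is anti-conservative (as any
  Poisson-family test would be). The generator's null calibration checks
  exactly the paired regime.
* The binding caller ignores control-count noise in λ (a property inherited
  from local-λ Poisson callers generally); the smoothed 10 kb term and the
  max() floor mitigate but do not remove this.
* Genome-scale gene counts from the original study depend on raw sequencing
  data, read alignment and different caller internals, and are outside what
  this artifact reproduces; all comparisons here are property-based on
  synthetic data.
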