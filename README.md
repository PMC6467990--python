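# primedchip

Stage-lagged chromatin–expression ("gene priming") analysis for differential
ChIP-seq / RNA-seq time courses.

## The problem

During two-step plant regeneration, explants first form a pluripotent callus
on auxin-rich medium (stages C0 → C14) and are then transferred to
cytokinin-rich shoot-induction medium (C14S1, C14S7). A histone H3K4
demethylase removes H3K4me2 from its target genes *during callus formation*,
yet the phenotypic consequence appears only *after* shoot induction: in the
demethylase mutant, target genes carry excess H3K4me2 at C14 with unchanged
concurrent expression, and then fail to activate at C14S1. This is epigenetic
**priming** — a chromatin change at one stage that predicts the expression
response at a later stage.

`primedchip` implements the full integrative analysis that detects this
signature from per-gene count data, together with a synthetic-data generator
that emulates the study design (2 genotypes × 4 stages; RNA-seq in biological
triplicate, ChIP-seq in duplicate), so every stage of the pipeline is testable
against known ground truth.

## What the pipeline computes

For genes *g* with counts normalized to RPM/RPKM over genic regions (gene
body ± 2 kb):

1. **Stage-response sets** (wild type): UGs/DGs at S1 and S7 with
   FC > 1.25 or < 0.8 at BH q < 0.01, from a paired count test — per
   replicate *k*, a_k vs b_k is tested against the library-size null
   proportion π_k = A_k/(A_k+B_k) with an exact binomial upper tail,
   per-replicate normal scores z_k = Φ⁻¹(1−p_k) are Stouffer-combined
   (Z = Σz_k/√K), and a two-sided p follows from Z.
2. **Hyper-mark genes**: mutant/WT mark ratio > 1.5 at q < 0.01 (generic
   over assay; used for H3K4me2 and H3K27me3).
3. **Bound genes**: windowed local-λ Poisson enrichment of TF ChIP over a
   scaled control (λ = max of window control, smoothed 10 kb control,
   genome-wide rate), BH across all windows, peaks at q < 0.1 merged and
   assigned to genes via genic regions.
4. **Mark-change groups**: Δme2 = log₂(mutant/WT RPKM) at C14 on
   half-minimum-pseudocounted values; group i: Δ < 0, ii: 0 ≤ Δ ≤ 1,
   iii: Δ > 1. Per group, a paired Wilcoxon signed-rank test (exact sign-flip
   enumeration for n ≤ 25) compares the expression ratio at C14 against
   C14S1 — the lag test.
5. **me-state stratification**: me1±/me3± classes at > 20 RPKM in WT callus;
   the grouped lag analysis and the Pearson correlation r(Δme2, Δexpr) are
   repeated per class within bound genes.
6. **Target selection**: the four-way intersection
   hyper-me2 ∩ UGs_S1 ∩ down-in-mutant-S1 ∩ bound, with full Venn
   cardinalities, plus metagene positional profiles and WT-C14-normalized
   relative-expression heat-map tables.

## Worked example

Run the numbered drivers in `analysis/` (each writes under `results/run/` and
can also be driven through the `primedchip` CLI, e.g.
`primedchip all --outdir results/run --seed 1`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/03_call_binding.py
python analysis/06_lag_analysis.py
python analysis/07_select_targets.py
```

prints (abridged):

```
truth: 200 primed, 600 bound, 400 induced at S1, 200 repressed
bound genes called: 600 (truth: 600)  sensitivity 1.000, precision 1.000
correlation of the me2 change with the expression change:
  r_dme2_dexpr_C14 = -0.006
  r_dme2_dexpr_C14S1 = -0.850
group    n      p_value  neg_log10_p
    i  888 7.647853e-01     0.116460
   ii 1031 1.011094e-12    11.995209
  iii   81 5.463819e-15    14.262504
  me1+me3+: n=287, r_C14=0.054, r_C14S1=-0.929
selected targets: 198 (true primed genes: 200)
sensitivity 0.990, precision 1.000
```

Reading: the mutant's H3K4me2 excess at C14 does not correlate with the
concurrent expression change (r ≈ 0) but strongly anti-correlates with the
expression change one day after induction (r = −0.85) — the lag signature.
The signal concentrates in groups ii/iii (genes with elevated me2) and, among
bound genes, exclusively in the me1⁺me3⁺ stratum, and the four-way
intersection recovers 198 of the 200 genes the simulator primed, with no
false targets.

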