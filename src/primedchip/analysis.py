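"""One-call, in-memory end-to-end analysis of a dataset.

Chains binding calls, stage-response sets, hyper-mark detection, ratio
matrices, grouping, lag tests, me-state stratification and target selection
into a single result object.  The file-based stages in :mod:`.workflow`
produce the same quantities artifact by artifact; this entry point serves
programmatic use (tests, notebooks, the acceptance script).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .binding import call_bound_genes
from .intervals import extend_reads, genic_regions
from .priming import (
    AnalysisThresholds,
    condition_means,
    down_in_mutant_set,
    genotype_log2_ratio,
    hyper_mark_genes,
    lag_association_test,
    mark_change_groups,
    me_state_classify,
    pearson,
    pseudocounted_rpkm,
    select_primed_targets,
    stage_response_sets,
    stratified_lag_analysis,
)
from .simulate import SimulatedDataset


@dataclass
class AnalysisResult:
    bound: set[str] = field(default_factory=set)
    hyper_me2: set[str] = field(default_factory=set)
    response_sets: dict[str, set[str]] = field(default_factory=dict)
    down_in_mutant_s1: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    venn: pd.DataFrame | None = None
    delta_me2: pd.Series | None = None
    expr_ratio_c14: pd.Series | None = None
    expr_ratio_s1: pd.Series | None = None
    groups: pd.Series | None = None
    me_states: pd.Series | None = None
    lag_tests: pd.DataFrame | None = None
    stratified: dict | None = None
    correlations: dict[str, float] = field(default_factory=dict)


def call_binding(ds: SimulatedDataset, thresholds: AnalysisThresholds,
                 width: int = 500, step: int = 250) -> set[str]:
    """Pool TF replicates, extend, and call the bound-gene set."""
    regions = genic_regions(ds.genes, thresholds.flank, ds.chrom_lengths)
    treat = pd.concat(
        [r for sid, r in sorted(ds.tf_reads.items()) if "TF-ChIP" in sid], ignore_index=True
    )
    control = pd.concat(
        [r for sid, r in sorted(ds.tf_reads.items()) if "TF-control" in sid], ignore_index=True
    )
    treat = extend_reads(treat, thresholds.fragment_length, ds.chrom_lengths)
    control = extend_reads(control, thresholds.fragment_length, ds.chrom_lengths)
    bound, _, _ = call_bound_genes(
        treat, control, ds.chrom_lengths, regions,
        width=width, step=step, q_threshold=thresholds.binding_q,
    )
    return bound


def analyze_dataset(
    ds: SimulatedDataset,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    window_width: int = 500,
    window_step: int = 250,
) -> AnalysisResult:
    res = AnalysisResult()
    res.bound = call_binding(ds, thresholds, window_width, window_step)
    res.hyper_me2, _ = hyper_mark_genes(ds.chip, "H3K4me2", "C14", thresholds)
    res.response_sets, _ = stage_response_sets(ds.rna, thresholds)
    res.down_in_mutant_s1, _ = down_in_mutant_set(ds.rna, "C14S1", thresholds)
    res.targets, res.venn = select_primed_targets(
        res.hyper_me2, res.response_sets["UGs_S1"], res.down_in_mutant_s1,
        res.bound, ds.genes["gene_id"],
    )
    res.delta_me2 = genotype_log2_ratio(ds.chip, "H3K4me2", "C14")
    res.expr_ratio_c14 = genotype_log2_ratio(ds.rna, "RNA", "C14")
    res.expr_ratio_s1 = genotype_log2_ratio(ds.rna, "RNA", "C14S1")
    res.groups = mark_change_groups(res.delta_me2, thresholds.group_bounds)
    res.lag_tests = lag_association_test(res.groups, res.expr_ratio_c14, res.expr_ratio_s1)
    me1 = condition_means(pseudocounted_rpkm(ds.chip, "H3K4me1"))["WT_C14"]
    me3 = condition_means(pseudocounted_rpkm(ds.chip, "H3K4me3"))["WT_C14"]
    res.me_states = me_state_classify(me1, me3, thresholds.me_state_rpkm)
    res.stratified = stratified_lag_analysis(
        res.bound, res.me_states, res.delta_me2, res.expr_ratio_c14, res.expr_ratio_s1
    )
    res.correlations = {
        "r_dme2_dexpr_C14": pearson(res.delta_me2, res.expr_ratio_c14, "log2ratio").r,
        "r_dme2_dexpr_C14S1": pearson(res.delta_me2, res.expr_ratio_s1, "log2ratio").r,
    }
    return res
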