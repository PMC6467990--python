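"""The integrative priming analysis.

The question these operations answer: which genes carry a histone-mark change
in the mutant at the callus stage (C14) that leaves concurrent expression
unchanged but predicts a failed expression response after shoot induction
(C14S1)?  The building blocks are

* stage-response gene sets in wild type (UGs/DGs at S1 and S7),
* hyper-mark genes (mutant/WT mark ratio > 1.5 at BH q < 0.01),
* per-gene log2 mutant/WT ratio matrices on pseudocounted RPKM,
* grouping of the me2 change (i: < 0, ii: 0..1, iii: > 1) with a
  stage-lagged Wilcoxon comparison of the expression ratios,
* me1/me3 presence classes (> 20 RPKM) used to stratify bound genes,
* and the four-way intersection that selects candidate primed targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .stats import (
    NormalizedMatrix,
    add_half_min_pseudocount,
    bh_adjust,
    log2_ratio,
    paired_count_test_matrix,
    pearson,
    rpkm_matrix,
    rpm_matrix,
    wilcoxon_signed_rank,
    zscore_rows,
)

ME_CLASSES = ("me1-me3-", "me1+me3-", "me1-me3+", "me1+me3+")
GROUPS = ("i", "ii", "iii")


@dataclass(frozen=True)
class AnalysisThresholds:
    """All cutoffs of the analysis, at the study's published values."""

    deg_fc_up: float = 1.25
    deg_fc_down: float = 0.8
    deg_p: float = 0.01  # BH q cutoff for DEG calls
    hyper_ratio: float = 1.5
    hyper_p: float = 0.01  # BH q cutoff for hyper-mark calls
    binding_q: float = 0.1
    me_state_rpkm: float = 20.0
    flank: int = 2000
    fragment_length: int = 250
    group_bounds: tuple[float, float] = (0.0, 1.0)  # log2 scale

    def __post_init__(self) -> None:
        if not self.deg_fc_down < 1.0 < self.deg_fc_up:
            raise ValueError("require deg_fc_down < 1 < deg_fc_up")
        for name in ("deg_p", "hyper_p", "binding_q", "me_state_rpkm", "hyper_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class GeneSetCollection:
    """Named gene sets over a shared universe."""

    def __init__(self, universe) -> None:
        self.universe = set(universe)
        self.sets: dict[str, set[str]] = {}

    def add(self, name: str, members) -> None:
        members = set(members)
        stray = members - self.universe
        if stray:
            raise ValueError(f"set {name!r} has members outside the universe: {sorted(stray)[:5]}")
        self.sets[name] = members

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def venn_counts(self, names: list[str]) -> pd.DataFrame:
        """Cardinality of every membership cell over the union of the sets."""
        union = set().union(*(self.sets[n] for n in names))
        rows = []
        for pattern in product([True, False], repeat=len(names)):
            if not any(pattern):
                continue
            cell = union.copy()
            for name, inside in zip(names, pattern):
                cell &= self.sets[name] if inside else (union - self.sets[name])
            rows.append(["".join("1" if b else "0" for b in pattern), len(cell)])
        return pd.DataFrame(rows, columns=["membership_" + "_".join(names), "n"])

    def write(self, name: str, path: str | Path) -> None:
        pd.Series(sorted(self.sets[name]), name="gene_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ratio matrices (pseudocounted RPKM, replicate-averaged)
# ---------------------------------------------------------------------------

def pseudocounted_rpkm(cm: CountMatrix, assay: str) -> NormalizedMatrix:
    """RPKM over every sample of one assay, with a single half-minimum offset.

    The pseudocount is taken over the whole assay matrix so that ratios at
    different stages share one offset, matching a pseudocount applied to all
    values prior to any other procedure.
    """
    sub = cm.select(assay=assay)
    return add_half_min_pseudocount(rpkm_matrix(sub))


def condition_means(norm: NormalizedMatrix) -> pd.DataFrame:
    """Replicate-averaged values per (genotype, stage) condition."""
    cols: dict[str, pd.Series] = {}
    for s in norm.samples:
        cols.setdefault(f"{s.genotype}_{s.stage}", []).append(s.sample_id)
    return pd.DataFrame(
        {cond: norm.values[ids].mean(axis=1) for cond, ids in cols.items()}
    )


def genotype_log2_ratio(cm: CountMatrix, assay: str, stage: str) -> pd.Series:
    """Per-gene log2(mutant/WT) of replicate-averaged pseudocounted RPKM."""
    norm = pseudocounted_rpkm(cm, assay)
    means = condition_means(norm)
    return log2_ratio(means[f"mutant_{stage}"], means[f"WT_{stage}"])


# ---------------------------------------------------------------------------
# Gene-set construction
# ---------------------------------------------------------------------------

def _deg_test(cm_a: CountMatrix, cm_b: CountMatrix) -> pd.DataFrame:
    """Paired test of a vs b (replicates matched by index), with BH q."""
    if cm_a.counts.shape[1] != cm_b.counts.shape[1]:
        raise ValueError("replicate structure differs between conditions")
    return paired_count_test_matrix(
        cm_a.counts, cm_b.counts,
        cm_a.library_sizes.to_numpy(), cm_b.library_sizes.to_numpy(),
    )


def stage_response_sets(
    rna: CountMatrix, thresholds: AnalysisThresholds = AnalysisThresholds()
) -> tuple[dict[str, set[str]], dict[str, pd.DataFrame]]:
    """WT up/down-regulated gene sets for C14->C14S1 and C14->C14S7.

    UGs = {q < deg_p and FC > deg_fc_up}, DGs = {q < deg_p and FC < deg_fc_down},
    with FC the pseudocounted mean-RPM ratio of the later stage over C14.
    """
    wt = rna.select(genotype="WT", assay="RNA")
    sets: dict[str, set[str]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for stage, label in (("C14S1", "S1"), ("C14S7", "S7")):
        try:
            later = wt.sorted_replicates("WT", stage, "RNA")
            base = wt.sorted_replicates("WT", "C14", "RNA")
        except ValueError as exc:
            raise ValueError(f"missing WT RNA samples for stage {stage}") from exc
        res = _deg_test(later, base)
        sig = res["q_value"] < thresholds.deg_p
        sets[f"UGs_{label}"] = set(res.index[sig & (res["effect"] > thresholds.deg_fc_up)])
        sets[f"DGs_{label}"] = set(res.index[sig & (res["effect"] < thresholds.deg_fc_down)])
        tables[label] = res
    return sets, tables


def hyper_mark_genes(
    chip: CountMatrix,
    assay: str = "H3K4me2",
    stage: str = "C14",
    thresholds: AnalysisThresholds = AnalysisThresholds(),
) -> tuple[set[str], pd.DataFrame]:
    """Genes with elevated mark in the mutant: ratio > 1.5 at BH q < 0.01.

    Generic over assay (reused for H3K27me3).
    """
    try:
        mut = chip.sorted_replicates("mutant", stage, assay)
        wt = chip.sorted_replicates("WT", stage, assay)
    except ValueError as exc:
        raise ValueError(f"missing {assay} duplicates for a genotype at {stage}") from exc
    res = _deg_test(mut, wt)
    hyper = set(
        res.index[(res["q_value"] < thresholds.hyper_p) & (res["effect"] > thresholds.hyper_ratio)]
    )
    return hyper, res


def down_in_mutant_set(
    rna: CountMatrix, stage: str = "C14S1",
    thresholds: AnalysisThresholds = AnalysisThresholds(),
) -> tuple[set[str], pd.DataFrame]:
    """Genes expressed lower in the mutant than WT at a stage (q < 0.01, FC < 0.8)."""
    try:
        mut = rna.sorted_replicates("mutant", stage, "RNA")
        wt = rna.sorted_replicates("WT", stage, "RNA")
    except ValueError as exc:
        raise ValueError(f"missing RNA triplicates for a genotype at {stage}") from exc
    res = _deg_test(mut, wt)
    members = set(
        res.index[(res["q_value"] < thresholds.deg_p) & (res["effect"] < thresholds.deg_fc_down)]
    )
    return members, res


# ---------------------------------------------------------------------------
# Grouping and stage-lagged tests
# ---------------------------------------------------------------------------

def mark_change_groups(
    delta_me2: pd.Series, bounds: tuple[float, float] = (0.0, 1.0)
) -> pd.Series:
    """Assign each gene to group i (< lo), ii (lo..hi, closed), or iii (> hi)."""
    lo, hi = bounds
    labels = np.where(delta_me2 < lo, "i", np.where(delta_me2 > hi, "iii", "ii"))
    return pd.Series(labels, index=delta_me2.index, name="group")


def lag_association_test(
    groups: pd.Series, expr_ratio_c14: pd.Series, expr_ratio_s1: pd.Series
) -> pd.DataFrame:
    """Per group: paired Wilcoxon of the C14 vs C14S1 expression ratios.

    Also reports a one-sample Wilcoxon of each stage's ratios against zero.
    Groups with fewer than two genes are reported as NA rows.
    """
    rows = []
    for grp in GROUPS:
        members = groups.index[groups == grp]
        n = len(members)
        if n < 2:
            rows.append([grp, n] + [np.nan] * 7)
            continue
        x = expr_ratio_c14.loc[members].to_numpy()
        y = expr_ratio_s1.loc[members].to_numpy()
        paired = wilcoxon_signed_rank(x, y)
        one_c14 = wilcoxon_signed_rank(x)
        one_s1 = wilcoxon_signed_rank(y)
        rows.append(
            [
                grp, n, paired.statistic, paired.p_value,
                -np.log10(max(paired.p_value, 1e-300)),
                one_c14.p_value, one_s1.p_value,
                float(np.median(x)), float(np.median(y)),
            ]
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "n", "W", "p_value", "neg_log10_p",
            "p_vs_zero_C14", "p_vs_zero_C14S1", "median_C14", "median_C14S1",
        ],
    )


def me_state_classify(
    me1_rpkm: pd.Series, me3_rpkm: pd.Series, threshold: float = 20.0
) -> pd.Series:
    """Partition genes into me1+-/me3+- classes; positive iff RPKM > threshold (strict)."""
    me1 = me1_rpkm > threshold
    me3 = me3_rpkm > threshold
    labels = np.where(
        me1, np.where(me3, "me1+me3+", "me1+me3-"), np.where(me3, "me1-me3+", "me1-me3-")
    )
    return pd.Series(labels, index=me1_rpkm.index, name="me_class")


def stratified_lag_analysis(
    bound: set[str],
    me_states: pd.Series,
    delta_me2: pd.Series,
    expr_ratio_c14: pd.Series,
    expr_ratio_s1: pd.Series,
) -> dict[str, dict]:
    """The grouped lag analysis restricted to bound genes, per me-state class.

    For each class: group sizes, the per-group lag tests, and the Pearson
    correlation of the me2 change with the expression change at each stage.
    """
    report: dict[str, dict] = {}
    bound_idx = me_states.index.intersection(sorted(bound))
    for cls in ME_CLASSES:
        members = bound_idx[me_states.loc[bound_idx] == cls]
        entry: dict = {"n": int(len(members))}
        if len(members) < 3:
            entry.update(groups=None, r_C14=np.nan, r_C14S1=np.nan)
            report[cls] = entry
            continue
        d = delta_me2.loc[members]
        groups = mark_change_groups(d)
        entry["group_sizes"] = groups.value_counts().reindex(GROUPS, fill_value=0).to_dict()
        entry["lag_tests"] = lag_association_test(
            groups, expr_ratio_c14.loc[members], expr_ratio_s1.loc[members]
        )
        entry["r_C14"] = pearson(d, expr_ratio_c14.loc[members], "log2ratio").r
        entry["r_C14S1"] = pearson(d, expr_ratio_s1.loc[members], "log2ratio").r
        report[cls] = entry
    return report


def mark_stage_delta(
    chip: CountMatrix, assay: str, genotype: str, stage_x: str, stage_y: str
) -> pd.Series:
    """Per-gene sqrt(RPM) difference between two stages (replicate-averaged)."""
    norm = rpm_matrix(chip.select(assay=assay, genotype=genotype))
    means = condition_means(norm)
    for stage in (stage_x, stage_y):
        if f"{genotype}_{stage}" not in means.columns:
            raise ValueError(f"missing {assay} samples for {genotype} at {stage}")
    return np.sqrt(means[f"{genotype}_{stage_y}"]) - np.sqrt(means[f"{genotype}_{stage_x}"])


def select_primed_targets(
    hyper_me2: set[str], ugs_s1: set[str], down_in_mutant: set[str], bound: set[str],
    universe,
) -> tuple[set[str], pd.DataFrame]:
    """Four-way intersection selecting candidate primed targets, plus Venn cells."""
    coll = GeneSetCollection(universe)
    coll.add("hyper_me2", hyper_me2)
    coll.add("UGs_S1", ugs_s1)
    coll.add("down_in_mutant_S1", down_in_mutant)
    coll.add("bound", bound)
    targets = hyper_me2 & ugs_s1 & down_in_mutant & bound
    venn = coll.venn_counts(["hyper_me2", "UGs_S1", "down_in_mutant_S1", "bound"])
    return targets, venn


# ---------------------------------------------------------------------------
# Display tables
# ---------------------------------------------------------------------------

def relative_expression_table(rna: CountMatrix, genes) -> pd.DataFrame:
    """Heat-map-ready row z-scores of WT-C14-normalised relative expression.

    Pseudocounted RPM is replicate-averaged per condition, divided by the
    WT-C14 value per gene, and z-scored across conditions.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in rna.gene_ids]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:10]}")
    norm = add_half_min_pseudocount(rpm_matrix(rna.select(assay="RNA")))
    means = condition_means(norm).loc[genes]
    rel = means.div(means["WT_C14"], axis=0)
    z = zscore_rows(NormalizedMatrix(rel, scale="RPM"))
    return z.values


def expression_by_me_state(
    expr_rpkm: pd.Series,
    me_states: pd.Series,
    me2_pos: pd.Series | None = None,
) -> pd.DataFrame:
    """Median and quartiles of log2 expression per me-mark presence class.

    With ``me2_pos`` the four me1/me3 classes are split further by me2
    presence (all eight combinations); empty classes yield NA rows.
    """
    log_expr = np.log2(expr_rpkm + expr_rpkm[expr_rpkm > 0].min() / 2)
    if me2_pos is None:
        labels = me_states
        all_labels = list(ME_CLASSES)
    else:
        labels = me_states + np.where(me2_pos, " me2+", " me2-")
        all_labels = [f"{c} {m}" for c in ME_CLASSES for m in ("me2-", "me2+")]
    rows = []
    for cls in all_labels:
        vals = log_expr[labels == cls]
        if len(vals) == 0:
            rows.append([cls, 0, np.nan, np.nan, np.nan])
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append([cls, len(vals), q1, med, q3])
    return pd.DataFrame(rows, columns=["class", "n", "q1", "median", "q3"])


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class PrimingReport:
    """Assembled results of the full analysis, serialisable to JSON."""

    set_sizes: dict[str, int] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)
    lag_tests: pd.DataFrame | None = None
    stratified: dict[str, dict] | None = None
    targets: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, pd.DataFrame):
                return json.loads(obj.to_json(orient="records"))
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, float)):
                return None if np.isnan(obj) else float(obj)
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            return obj

        return {
            "set_sizes": clean(self.set_sizes),
            "correlations": clean(self.correlations),
            "lag_tests": clean(self.lag_tests) if self.lag_tests is not None else None,
            "stratified": clean(self.stratified) if self.stratified is not None else None,
            "targets": sorted(self.targets),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
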