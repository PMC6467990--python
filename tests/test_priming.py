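"""Integrative analysis operations: sets, groups, me-states, lag tests, targets."""

import numpy as np
import pandas as pd
import pytest

from primedchip.containers import CountMatrix, SampleDescriptor, make_sample_id
from primedchip.priming import (
    AnalysisThresholds,
    GeneSetCollection,
    down_in_mutant_set,
    expression_by_me_state,
    genotype_log2_ratio,
    hyper_mark_genes,
    lag_association_test,
    mark_change_groups,
    mark_stage_delta,
    me_state_classify,
    relative_expression_table,
    select_primed_targets,
    stage_response_sets,
)


def tiny_rna_matrix(per_condition_counts, replicates=3, genes=("gA", "gB")):
    """CountMatrix from {(genotype, stage): [per-gene counts]} with equal replicates."""
    cols, samples = {}, []
    for (genotype, stage), vals in per_condition_counts.items():
        for k in range(1, replicates + 1):
            sid = make_sample_id(genotype, stage, "RNA", k)
            cols[sid] = vals
            samples.append(SampleDescriptor(sid, genotype, stage, "RNA", k, 1000))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return CountMatrix(counts, samples, pd.Series(1000, index=counts.index))


class TestThresholds:
    def test_defaults_are_the_published_cutoffs(self):
        t = AnalysisThresholds()
        assert (t.deg_fc_up, t.deg_fc_down, t.deg_p) == (1.25, 0.8, 0.01)
        assert (t.hyper_ratio, t.hyper_p, t.binding_q) == (1.5, 0.01, 0.1)
        assert (t.me_state_rpkm, t.flank, t.fragment_length) == (20.0, 2000, 250)

    def test_invalid_fold_change_ordering_rejected(self):
        with pytest.raises(ValueError):
            AnalysisThresholds(deg_fc_down=1.5)


class TestMarkChangeGroups:
    def test_interval_assignment(self):
        delta = pd.Series({"a": -0.5, "b": 0.5, "c": 1.5})
        assert mark_change_groups(delta).tolist() == ["i", "ii", "iii"]

    def test_boundaries_belong_to_middle_group(self):
        delta = pd.Series({"a": 0.0, "b": 1.0})
        assert mark_change_groups(delta).tolist() == ["ii", "ii"]

    def test_every_gene_in_exactly_one_group(self):
        rng = np.random.default_rng(0)
        delta = pd.Series(rng.normal(0.5, 1.0, 500))
        groups = mark_change_groups(delta)
        assert groups.isin(["i", "ii", "iii"]).all()
        assert groups.value_counts().sum() == 500


class TestMeStateClassify:
    def test_example_assignments(self):
        me1 = pd.Series({"a": 25.0, "b": 20.0, "c": 5.0})
        me3 = pd.Series({"a": 5.0, "b": 25.0, "c": 30.0})
        got = me_state_classify(me1, me3)
        assert got["a"] == "me1+me3-"
        assert got["b"] == "me1-me3+"  # exactly 20 is negative (strict >)
        assert got["c"] == "me1-me3+"

    def test_classes_partition_universe(self):
        rng = np.random.default_rng(1)
        me1 = pd.Series(rng.exponential(25, 300))
        me3 = pd.Series(rng.exponential(25, 300))
        classes = me_state_classify(me1, me3)
        assert classes.value_counts().sum() == 300


class TestLagAssociationTest:
    def test_identical_ratios_give_p_one(self):
        groups = pd.Series("ii", index=[f"g{i}" for i in range(6)])
        x = pd.Series(np.linspace(-1, 1, 6), index=groups.index)
        out = lag_association_test(groups, x, x.copy())
        row = out[out["group"] == "ii"].iloc[0]
        assert row["p_value"] == 1.0

    def test_five_gene_shift_exact_p(self):
        # C14 ratios all 0, C14S1 ratios all -1: p = 2/32 by sign enumeration
        idx = [f"g{i}" for i in range(5)]
        groups = pd.Series("iii", index=idx)
        c14 = pd.Series(0.0, index=idx)
        s1 = pd.Series(-1.0, index=idx)
        out = lag_association_test(groups, c14, s1)
        row = out[out["group"] == "iii"].iloc[0]
        assert row["p_value"] == pytest.approx(2 / 32)

    def test_small_groups_reported_as_na(self):
        groups = pd.Series({"g0": "i"})
        out = lag_association_test(groups, pd.Series({"g0": 1.0}), pd.Series({"g0": 2.0}))
        assert np.isnan(out[out["group"] == "i"]["p_value"].iloc[0])
        assert np.isnan(out[out["group"] == "iii"]["p_value"].iloc[0])


class TestGeneSetCollection:
    def test_member_outside_universe_rejected(self):
        coll = GeneSetCollection(["a", "b"])
        with pytest.raises(ValueError):
            coll.add("s", ["a", "z"])

    def test_venn_cells_partition_union(self):
        coll = GeneSetCollection(list("abcdef"))
        coll.add("x", ["a", "b", "c"])
        coll.add("y", ["b", "c", "d"])
        venn = coll.venn_counts(["x", "y"])
        assert venn["n"].sum() == 4  # |union|


class TestSelectPrimedTargets:
    def test_set_algebra_example(self):
        universe = list("ABCD")
        targets, venn = select_primed_targets(
            {"A", "B", "C"}, {"B", "C"}, {"B", "C", "D"}, {"C"}, universe
        )
        assert targets == {"C"}
        assert venn["n"].sum() == 4  # union of the four sets

    def test_any_empty_input_gives_empty_output(self):
        targets, _ = select_primed_targets({"A"}, set(), {"A"}, {"A"}, ["A"])
        assert targets == set()


class TestStageResponseSets:
    def test_missing_stage_raises(self):
        cm = tiny_rna_matrix({("WT", "C14"): [10, 10], ("WT", "C14S1"): [10, 10]})
        with pytest.raises(ValueError, match="C14S7"):
            stage_response_sets(cm)

    def test_unchanged_gene_in_neither_set(self):
        cm = tiny_rna_matrix(
            {
                ("WT", "C14"): [100, 100],
                ("WT", "C14S1"): [100, 100],
                ("WT", "C14S7"): [100, 100],
            }
        )
        sets, _ = stage_response_sets(cm)
        assert all(len(s) == 0 for s in sets.values())

    def test_induced_genes_recovered_with_high_sensitivity(self, default_sim, default_truth):
        sets, tables = stage_response_sets(default_sim.rna)
        induced = set(default_truth.index[default_truth["induced"]])
        sens = len(sets["UGs_S1"] & induced) / len(induced)
        assert sens >= 0.9
        # members satisfy the published thresholds
        table = tables["S1"].loc[sorted(sets["UGs_S1"])]
        assert (table["q_value"] < 0.01).all()
        assert (table["effect"] > 1.25).all()

    def test_ugs_dgs_disjoint_at_each_stage(self, default_sim):
        sets, _ = stage_response_sets(default_sim.rna)
        assert not (sets["UGs_S1"] & sets["DGs_S1"])
        assert not (sets["UGs_S7"] & sets["DGs_S7"])


class TestHyperMarkGenes:
    def test_identical_genotypes_give_empty_set(self, small_sim):
        from primedchip.simulate import SimConfig, null_dataset

        ds = null_dataset(SimConfig(n_genes=300, n_chroms=3, seed=3))
        hyper, _ = hyper_mark_genes(ds.chip)
        assert hyper == set()

    def test_threshold_semantics_on_members(self, default_sim):
        hyper, table = hyper_mark_genes(default_sim.chip)
        members = table.loc[sorted(hyper)]
        assert (members["q_value"] < 0.01).all()
        assert (members["effect"] > 1.5).all()
        non = table.drop(index=sorted(hyper))
        assert (~((non["q_value"] < 0.01) & (non["effect"] > 1.5))).all()

    def test_generic_over_assay(self, small_sim):
        hyper_k27, _ = hyper_mark_genes(small_sim.chip, assay="H3K27me3")
        assert isinstance(hyper_k27, set)

    def test_missing_genotype_raises(self, small_sim):
        wt_only = small_sim.chip.select(genotype="WT")
        with pytest.raises(ValueError, match="H3K4me2"):
            hyper_mark_genes(wt_only)


class TestDownInMutant:
    def test_attenuated_primed_genes_recovered(self, default_sim, default_truth):
        down, table = down_in_mutant_set(default_sim.rna, "C14S1")
        primed = set(default_truth.index[default_truth["primed"]])
        assert len(down & primed) / len(primed) >= 0.8
        members = table.loc[sorted(down)]
        assert (members["effect"] < 0.8).all()


class TestMarkStageDelta:
    def test_same_stage_gives_zero(self, small_sim):
        delta = mark_stage_delta(small_sim.chip, "H3K4me2", "WT", "C14", "C14")
        assert np.allclose(delta, 0.0)

    def test_hand_arithmetic_fixture(self):
        cols, samples = {}, []
        for stage, vals in (("C0", [4, 16]), ("C14", [16, 64])):
            for k in (1, 2):
                sid = make_sample_id("WT", stage, "H3K4me2", k)
                cols[sid] = vals
                samples.append(SampleDescriptor(sid, "WT", stage, "H3K4me2", k, 10**6))
        cm = CountMatrix(
            pd.DataFrame(cols, index=pd.Index(["a", "b"], name="gene_id")),
            samples, pd.Series(1000, index=["a", "b"]),
        )
        delta = mark_stage_delta(cm, "H3K4me2", "WT", "C0", "C14")
        assert delta["a"] == pytest.approx(np.sqrt(16.0) - np.sqrt(4.0))
        assert delta["b"] == pytest.approx(np.sqrt(64.0) - np.sqrt(16.0))

    def test_genotype_delta_correlation_on_null(self):
        from primedchip.simulate import SimConfig, null_dataset
        from primedchip.stats import pearson

        ds = null_dataset(SimConfig(seed=17))
        d_wt = mark_stage_delta(ds.chip, "H3K4me2", "WT", "C0", "C14")
        d_mut = mark_stage_delta(ds.chip, "H3K4me2", "mutant", "C0", "C14")
        assert pearson(d_wt, d_mut).r >= 0.95


class TestRelativeExpressionTable:
    def test_two_gene_fixture_hand_computed(self):
        cm = tiny_rna_matrix(
            {
                ("WT", "C0"): [10, 40],
                ("WT", "C14"): [20, 20],
                ("WT", "C14S1"): [40, 10],
                ("WT", "C14S7"): [40, 10],
                ("mutant", "C0"): [10, 40],
                ("mutant", "C14"): [20, 20],
                ("mutant", "C14S1"): [20, 20],
                ("mutant", "C14S7"): [20, 20],
            }
        )
        # before z-scoring: WT_C14 column of the ratio table is exactly 1
        from primedchip.priming import condition_means
        from primedchip.stats import add_half_min_pseudocount, rpm_matrix

        means = condition_means(add_half_min_pseudocount(rpm_matrix(cm)))
        rel = means.div(means["WT_C14"], axis=0)
        assert np.allclose(rel["WT_C14"], 1.0)
        table = relative_expression_table(cm, ["gA", "gB"])
        assert np.allclose(table.mean(axis=1), 0.0, atol=1e-12)
        # gene A rises toward S1 in WT, gene B falls
        assert table.loc["gA", "WT_C14S1"] > table.loc["gA", "WT_C0"]
        assert table.loc["gB", "WT_C14S1"] < table.loc["gB", "WT_C0"]

    def test_missing_gene_raises_with_ids(self, small_sim):
        with pytest.raises(ValueError, match="missing_gene"):
            relative_expression_table(small_sim.rna, ["missing_gene"])


class TestExpressionByMeState:
    def test_equal_expression_gives_equal_medians(self):
        idx = [f"g{i}" for i in range(8)]
        expr = pd.Series(7.0, index=idx)
        classes = pd.Series(
            ["me1-me3-", "me1+me3-", "me1-me3+", "me1+me3+"] * 2, index=idx
        )
        out = expression_by_me_state(expr, classes)
        assert out["median"].nunique() == 1

    def test_me3_positive_classes_rank_higher(self, default_sim, default_analysis):
        from primedchip.priming import condition_means, pseudocounted_rpkm

        expr = condition_means(pseudocounted_rpkm(default_sim.rna, "RNA"))["WT_C14"]
        truth = default_sim.truth.set_index("gene_id")
        classes = pd.Series(truth["me_class"], index=truth.index)
        # give me3+ genes elevated expression and check the ordering surfaces
        boosted = expr * np.where(truth["me3_pos"], 4.0, 1.0)
        out = expression_by_me_state(pd.Series(boosted, index=expr.index), classes)
        med = out.set_index("class")["median"]
        assert med["me1-me3+"] > med["me1-me3-"]
        assert med["me1+me3+"] > med["me1+me3-"]

    def test_class_sizes_sum_to_universe(self):
        idx = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        expr = pd.Series(rng.exponential(10, 30), index=idx)
        classes = pd.Series(rng.choice(["me1-me3-", "me1+me3+"], 30), index=idx)
        me2 = pd.Series(rng.random(30) > 0.5, index=idx)
        out = expression_by_me_state(expr, classes, me2)
        assert out["n"].sum() == 30
        assert len(out) == 8  # all eight presence combinations reported


class TestGenotypeRatio:
    def test_primed_genes_center_near_me2_effect(self, default_sim, default_truth):
        delta = genotype_log2_ratio(default_sim.chip, "H3K4me2", "C14")
        primed = default_truth.index[default_truth["primed"]]
        others = default_truth.index[~default_truth["primed"]]
        assert abs(delta.loc[primed].median() - 1.0) < 0.15  # log2 of the 2x effect
        assert abs(delta.loc[others].median()) < 0.1
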