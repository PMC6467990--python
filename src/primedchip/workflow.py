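"""Re-entrant pipeline stages over a run directory, plus the run manifest.

Each stage reads only its declared inputs from conventional paths inside the
run directory and writes its outputs atomically (temp file, then rename).
The manifest records the configuration, package version and a SHA-256
checksum of every artifact, so two runs from the same seed can be compared
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import call_bound_genes, write_peaks_bed
from .containers import CountMatrix
from .intervals import count_overlaps, extend_reads, genic_regions, metagene_profile
from .priming import (
    AnalysisThresholds,
    PrimingReport,
    down_in_mutant_set,
    genotype_log2_ratio,
    hyper_mark_genes,
    lag_association_test,
    mark_change_groups,
    me_state_classify,
    pearson,
    pseudocounted_rpkm,
    condition_means,
    relative_expression_table,
    select_primed_targets,
    stage_response_sets,
    stratified_lag_analysis,
)
from .simulate import SimConfig, SimulatedDataset, simulate_dataset

log = logging.getLogger("primedchip")

SUBCOMMANDS = (
    "simulate", "count", "normalize", "bind", "respond",
    "hyper", "prime", "targets", "report", "all",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (thresholds validated on creation)."""

    outdir: Path
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    window_width: int = 500
    window_step: int = 250

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: Path, seed: int | None = None) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_kwargs = raw.get("sim", {})
        for key in ("gene_length_range", "gap_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        cfg = cls(
            outdir=outdir,
            seed=seed if seed is not None else raw.get("seed", 0),
            sim=SimConfig(**sim_kwargs),
            thresholds=AnalysisThresholds(**raw.get("thresholds", {})),
            window_width=raw.get("window_width", 500),
            window_step=raw.get("window_step", 250),
        )
        return cfg

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "sim": dataclasses.asdict(self.sim),
            "thresholds": dataclasses.asdict(self.thresholds),
            "window_width": self.window_width,
            "window_step": self.window_step,
        }
        return d


# ---------------------------------------------------------------------------
# Atomic output helpers
# ---------------------------------------------------------------------------

def _atomic_write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_df(path: Path, df: pd.DataFrame, **kwargs) -> None:
    _atomic_write_text(path, df.to_csv(sep="\t", **kwargs))


def _write_gene_set(path: Path, members) -> None:
    _atomic_write_df(path, pd.DataFrame({"gene_id": sorted(members)}), index=False)


def _read_gene_set(path: Path) -> set[str]:
    df = pd.read_csv(path, sep="\t")
    return set(df["gene_id"].astype(str))


def _require(outdir: Path, relpath: str) -> Path:
    path = outdir / relpath
    if not path.exists():
        raise FileNotFoundError(f"missing required artifact: {path}")
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(run: RunConfig) -> SimulatedDataset:
    log.info("simulate: %d genes, seed %d", run.sim.n_genes, run.sim.seed)
    dataset = simulate_dataset(run.sim)
    dataset.write(run.outdir / "sim")
    return dataset


def _load_dataset(run: RunConfig) -> SimulatedDataset:
    _require(run.outdir, "sim/truth.json")
    return SimulatedDataset.load(run.outdir / "sim")


def stage_count(run: RunConfig) -> pd.DataFrame:
    """Extend each emitted read track to fragment length and count per genic region."""
    ds = _load_dataset(run)
    regions = genic_regions(ds.genes, run.thresholds.flank, ds.chrom_lengths)
    cols = {}
    for sample_id, reads in sorted({**ds.tf_reads, **ds.mark_reads}.items()):
        ext = extend_reads(reads, run.thresholds.fragment_length, ds.chrom_lengths)
        cols[sample_id] = count_overlaps(ext, regions)
    counts = pd.DataFrame(cols, index=pd.Index(ds.genes["gene_id"], name="gene_id"))
    _atomic_write_df(run.outdir / "counts" / "read_counts.tsv", counts)
    log.info("count: %d samples counted over %d genic regions", len(cols), len(regions))
    return counts


def stage_normalize(run: RunConfig) -> None:
    ds = _load_dataset(run)
    from .stats import rpkm_matrix, rpm_matrix

    for name, cm in (("rna", ds.rna), ("chip", ds.chip)):
        _atomic_write_df(run.outdir / "normalize" / f"{name}_rpm.tsv", rpm_matrix(cm).values)
        _atomic_write_df(run.outdir / "normalize" / f"{name}_rpkm.tsv", rpkm_matrix(cm).values)
    log.info("normalize: wrote RPM/RPKM tables")


def stage_bind(run: RunConfig) -> set[str]:
    ds = _load_dataset(run)
    regions = genic_regions(ds.genes, run.thresholds.flank, ds.chrom_lengths)
    treat = pd.concat(
        [r for sid, r in sorted(ds.tf_reads.items()) if "TF-ChIP" in sid], ignore_index=True
    )
    control = pd.concat(
        [r for sid, r in sorted(ds.tf_reads.items()) if "TF-control" in sid], ignore_index=True
    )
    frag = run.thresholds.fragment_length
    treat = extend_reads(treat, frag, ds.chrom_lengths)
    control = extend_reads(control, frag, ds.chrom_lengths)
    bound, peaks, windows = call_bound_genes(
        treat, control, ds.chrom_lengths, regions,
        width=run.window_width, step=run.window_step,
        q_threshold=run.thresholds.binding_q,
    )
    outdir = run.outdir / "binding"
    outdir.mkdir(parents=True, exist_ok=True)
    write_peaks_bed(peaks, outdir / "peaks.bed")
    _write_gene_set(outdir / "bound_genes.tsv", bound)
    summary = pd.DataFrame(
        {
            "n_windows": [len(windows)],
            "n_significant": [int((windows["q_value"] < run.thresholds.binding_q).sum())],
            "n_peaks": [len(peaks)],
            "n_bound_genes": [len(bound)],
        }
    )
    _atomic_write_df(outdir / "summary.tsv", summary, index=False)
    log.info("bind: %d peaks, %d bound genes", len(peaks), len(bound))
    return bound


def stage_respond(run: RunConfig) -> dict[str, set[str]]:
    ds = _load_dataset(run)
    sets, tables = stage_response_sets(ds.rna, run.thresholds)
    outdir = run.outdir / "response"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, members in sets.items():
        _write_gene_set(outdir / f"{name}.tsv", members)
    for label, table in tables.items():
        _atomic_write_df(outdir / f"deg_{label}.tsv", table)
    log.info("respond: %s", {k: len(v) for k, v in sets.items()})
    return sets


def stage_hyper(run: RunConfig) -> set[str]:
    ds = _load_dataset(run)
    hyper, table = hyper_mark_genes(ds.chip, "H3K4me2", "C14", run.thresholds)
    outdir = run.outdir / "hyper"
    outdir.mkdir(parents=True, exist_ok=True)
    _write_gene_set(outdir / "hyper_me2_C14.tsv", hyper)
    _atomic_write_df(outdir / "hyper_me2_C14_stats.tsv", table)
    log.info("hyper: %d hyper-H3K4me2 genes at C14", len(hyper))
    return hyper


def stage_prime(run: RunConfig) -> dict:
    """Ratio matrices, groups, me-states, lag tests and stratified analysis."""
    ds = _load_dataset(run)
    bound = _read_gene_set(_require(run.outdir, "binding/bound_genes.tsv"))
    delta_me2 = genotype_log2_ratio(ds.chip, "H3K4me2", "C14")
    expr_c14 = genotype_log2_ratio(ds.rna, "RNA", "C14")
    expr_s1 = genotype_log2_ratio(ds.rna, "RNA", "C14S1")
    groups = mark_change_groups(delta_me2, run.thresholds.group_bounds)
    lag = lag_association_test(groups, expr_c14, expr_s1)

    wt_c14 = condition_means(pseudocounted_rpkm(ds.chip, "H3K4me1"))["WT_C14"]
    wt_c14_me3 = condition_means(pseudocounted_rpkm(ds.chip, "H3K4me3"))["WT_C14"]
    me_states = me_state_classify(wt_c14, wt_c14_me3, run.thresholds.me_state_rpkm)
    strat = stratified_lag_analysis(bound, me_states, delta_me2, expr_c14, expr_s1)

    correlations = {
        "r_dme2_dexpr_C14": pearson(delta_me2, expr_c14, "log2ratio").r,
        "r_dme2_dexpr_C14S1": pearson(delta_me2, expr_s1, "log2ratio").r,
    }
    outdir = run.outdir / "prime"
    outdir.mkdir(parents=True, exist_ok=True)
    per_gene = pd.DataFrame(
        {
            "delta_me2": delta_me2, "expr_ratio_C14": expr_c14,
            "expr_ratio_C14S1": expr_s1, "group": groups, "me_class": me_states,
        }
    )
    per_gene.index.name = "gene_id"
    _atomic_write_df(outdir / "per_gene.tsv", per_gene)
    _atomic_write_df(outdir / "lag_tests.tsv", lag, index=False)
    strat_clean = {
        cls: {
            "n": entry["n"],
            "group_sizes": entry.get("group_sizes"),
            "r_C14": None if pd.isna(entry["r_C14"]) else entry["r_C14"],
            "r_C14S1": None if pd.isna(entry["r_C14S1"]) else entry["r_C14S1"],
            "lag_tests": (
                json.loads(entry["lag_tests"].to_json(orient="records"))
                if entry.get("lag_tests") is not None
                else None
            ),
        }
        for cls, entry in strat.items()
    }
    _atomic_write_text(
        outdir / "stratified.json", json.dumps(strat_clean, indent=1, sort_keys=True)
    )
    _atomic_write_text(
        outdir / "correlations.json", json.dumps(correlations, indent=1, sort_keys=True)
    )
    log.info(
        "prime: r(dme2, dexpr) C14=%.3f C14S1=%.3f",
        correlations["r_dme2_dexpr_C14"], correlations["r_dme2_dexpr_C14S1"],
    )
    return {"lag": lag, "stratified": strat, "correlations": correlations}


def stage_targets(run: RunConfig) -> set[str]:
    ds = _load_dataset(run)
    bound = _read_gene_set(_require(run.outdir, "binding/bound_genes.tsv"))
    hyper = _read_gene_set(_require(run.outdir, "hyper/hyper_me2_C14.tsv"))
    ugs_s1 = _read_gene_set(_require(run.outdir, "response/UGs_S1.tsv"))
    down, down_table = down_in_mutant_set(ds.rna, "C14S1", run.thresholds)
    targets, venn = select_primed_targets(
        hyper, ugs_s1, down, bound, ds.genes["gene_id"]
    )
    outdir = run.outdir / "targets"
    outdir.mkdir(parents=True, exist_ok=True)
    _write_gene_set(outdir / "down_in_mutant_S1.tsv", down)
    _atomic_write_df(outdir / "down_in_mutant_S1_stats.tsv", down_table)
    _write_gene_set(outdir / "targets.tsv", targets)
    _atomic_write_df(outdir / "venn.tsv", venn, index=False)
    log.info("targets: %d candidate primed targets", len(targets))
    return targets


def stage_report(run: RunConfig) -> PrimingReport:
    ds = _load_dataset(run)
    targets = sorted(
        _read_gene_set(_require(run.outdir, "targets/targets.tsv"))
    )
    lag = pd.read_csv(_require(run.outdir, "prime/lag_tests.tsv"), sep="\t")
    correlations = json.loads(_require(run.outdir, "prime/correlations.json").read_text())
    stratified = json.loads(_require(run.outdir, "prime/stratified.json").read_text())
    set_sizes = {}
    for name, rel in (
        ("bound", "binding/bound_genes.tsv"),
        ("hyper_me2_C14", "hyper/hyper_me2_C14.tsv"),
        ("UGs_S1", "response/UGs_S1.tsv"),
        ("DGs_S1", "response/DGs_S1.tsv"),
        ("UGs_S7", "response/UGs_S7.tsv"),
        ("DGs_S7", "response/DGs_S7.tsv"),
        ("down_in_mutant_S1", "targets/down_in_mutant_S1.tsv"),
        ("selected_targets", "targets/targets.tsv"),
    ):
        set_sizes[name] = len(_read_gene_set(_require(run.outdir, rel)))
    report = PrimingReport(
        set_sizes=set_sizes, correlations=correlations, lag_tests=lag,
        stratified=stratified, targets=targets,
    )
    outdir = run.outdir / "report"
    outdir.mkdir(parents=True, exist_ok=True)
    report.write(outdir / "priming_report.json")
    if targets:
        table = relative_expression_table(ds.rna, targets)
        _atomic_write_df(outdir / "targets_relative_expression.tsv", table)
    log.info("report: assembled (%d targets)", len(targets))
    return report


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "count": stage_count,
    "normalize": stage_normalize,
    "bind": stage_bind,
    "respond": stage_respond,
    "hyper": stage_hyper,
    "prime": stage_prime,
    "targets": stage_targets,
    "report": stage_report,
}


def write_manifest(run: RunConfig) -> Path:
    """Record config, package version and SHA-256 of every artifact."""
    artifacts = {}
    for path in sorted(run.outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            artifacts[str(path.relative_to(run.outdir))] = digest
    manifest = {
        "version": __version__,
        "config": run.to_dict(),
        "artifacts": artifacts,
    }
    path = run.outdir / "manifest.json"
    _atomic_write_text(path, json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_pipeline(run: RunConfig, subcommand: str = "all"):
    """Execute one subcommand (or the full chain) and refresh the manifest."""
    if subcommand not in SUBCOMMANDS:
        raise ValueError(f"unknown subcommand {subcommand!r}; choose from {SUBCOMMANDS}")
    order = (
        ["simulate", "count", "normalize", "bind", "respond", "hyper", "prime", "targets", "report"]
        if subcommand == "all"
        else [subcommand]
    )
    result = None
    for name in order:
        result = STAGE_FUNCS[name](run)
    write_manifest(run)
    return result
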