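"""Synthetic datasets with the statistical structure the priming analysis assumes.

The generator emulates a two-genotype (wild type vs demethylase mutant),
four-stage (C0, C14, C14S1, C14S7) regeneration time course: RNA-seq in
biological triplicate, histone-mark ChIP-seq in biological duplicate, and a
TF ChIP/control pair at the callus stage.  A configurable subset of genes is
"primed": in the mutant their H3K4me2 is elevated at C14 and the elevation is
carried forward to C14S1, their concurrent expression is unchanged, but their
induction upon shoot induction (C14 -> C14S1) is attenuated.  Primed genes
are drawn from the bound, me1+me3+ portion of the genome by default,
mirroring where the demethylase's targets concentrate.

Counts follow a gamma-Poisson hierarchy: each (gene, assay, replicate index)
receives a gamma factor with unit mean and variance ``nb_dispersion`` that is
shared across genotypes and stages, and counts are Poisson around
baseline x condition-multiplier x factor.  Marginally the counts are negative
binomial with the configured dispersion; within a replicate pair the factor
cancels, which is exactly the situation a paired test is designed for.

All randomness flows from a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, SampleDescriptor, make_sample_id
from .intervals import genic_regions, read_bed_reads, write_bed_reads

CHIP_STAGES = ("C0", "C14", "C14S1")
RNA_STAGES = ("C0", "C14", "C14S1", "C14S7")
MARK_ASSAYS = ("H3", "H3K4me1", "H3K4me2", "H3K4me3", "H3K27me3")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic regeneration time course."""

    n_genes: int = 2000
    n_chroms: int = 5
    gene_length_range: tuple[int, int] = (1000, 3000)
    gap_range: tuple[int, int] = (4000, 6000)  # >= 4 kb so 2 kb flanks never merge
    priming_fraction: float = 0.1
    me2_effect: float = 2.0  # mutant/WT H3K4me2 multiplier at C14+ on primed genes
    induction_fc: float = 2.0  # WT S1/C14 expression fold on induced genes
    attenuation: float = 0.5  # mutant's induction multiplier on primed genes
    induced_fraction: float = 0.2  # genes induced at S1 (primed subset included)
    repressed_fraction: float = 0.1  # genes repressed at S1 in both genotypes
    bound_fraction: float = 0.3
    binding_enrichment: float = 4.0
    binding_skew: float = 0.75  # fraction of bound-gene TF reads in the 3' body half
    me1_fraction: float = 0.5
    me3_fraction: float = 0.5
    nb_dispersion: float = 0.05
    mean_count: float = 100.0  # per-gene expected count at baseline
    tf_mean_count: float = 50.0  # per-gene TF/control depth per replicate
    baseline_log_sd: float = 0.5  # log-normal spread of RNA baselines
    mark_log_sd: float = 0.3  # log-normal spread of mark baselines
    me2_callus_gain: float = 1.5  # mean per-gene me2 gain during callus formation
    rna_replicates: int = 3
    chip_replicates: int = 2
    fragment_length_emitted: int = 175  # pre-extension read length in BED output
    emit_mark_reads: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("priming_fraction", "bound_fraction", "me1_fraction", "me3_fraction",
                     "induced_fraction", "repressed_fraction", "binding_skew"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.attenuation <= 0 or self.attenuation > 1:
            raise ValueError("attenuation must lie in (0, 1]")
        if self.gap_range[0] < 4000:
            raise ValueError("gaps must be >= 4 kb so genic regions never merge")


@dataclass
class SimulatedDataset:
    config: SimConfig
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    chrom_lengths: dict[str, int]
    rna: CountMatrix
    chip: CountMatrix
    tf_reads: dict[str, pd.DataFrame]  # sample_id -> BED-like reads
    tf_samples: list[SampleDescriptor]
    mark_reads: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def all_samples(self) -> list[SampleDescriptor]:
        return self.rna.samples + self.chip.samples + self.tf_samples

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ann = self.genes[["chrom", "start", "end", "gene_id"]].copy()
        ann["score"] = 0
        ann["strand"] = self.genes["strand"]
        ann.to_csv(outdir / "annotation.bed", sep="\t", header=False, index=False)
        pd.Series(self.chrom_lengths, name="length").rename_axis("chrom").to_csv(
            outdir / "chrom_lengths.tsv", sep="\t"
        )
        self.rna.write(outdir / "counts_rna.tsv", outdir / "sample_sheet_rna.tsv")
        self.chip.write(outdir / "counts_chip.tsv", outdir / "sample_sheet_chip.tsv")
        from .containers import write_sample_sheet

        write_sample_sheet(self.all_samples, outdir / "sample_sheet.tsv")
        reads_dir = outdir / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sample_id, reads in {**self.tf_reads, **self.mark_reads}.items():
            write_bed_reads(reads, reads_dir / f"{sample_id}.bed")
        payload = {
            "config": dataclasses.asdict(self.config),
            "truth": {c: self.truth[c].tolist() for c in self.truth.columns},
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, outdir: str | Path) -> "SimulatedDataset":
        outdir = Path(outdir)
        payload = json.loads((outdir / "truth.json").read_text())
        cfg_dict = payload["config"]
        for k in ("gene_length_range", "gap_range"):
            cfg_dict[k] = tuple(cfg_dict[k])
        config = SimConfig(**cfg_dict)
        ann = pd.read_csv(
            outdir / "annotation.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
        )
        genes = ann[["gene_id", "chrom", "start", "end", "strand"]]
        chrom_lengths = (
            pd.read_csv(outdir / "chrom_lengths.tsv", sep="\t", index_col="chrom")["length"]
            .to_dict()
        )
        rna = CountMatrix.read(outdir / "counts_rna.tsv", outdir / "sample_sheet.tsv")
        chip = CountMatrix.read(outdir / "counts_chip.tsv", outdir / "sample_sheet.tsv")
        from .containers import read_sample_sheet

        all_samples = read_sample_sheet(outdir / "sample_sheet.tsv")
        tf_samples = [s for s in all_samples if s.assay in ("TF-ChIP", "TF-control")]
        tf_reads, mark_reads = {}, {}
        for bed in sorted((outdir / "reads").glob("*.bed")):
            reads = read_bed_reads(bed)
            if "TF" in bed.stem:
                tf_reads[bed.stem] = reads
            else:
                mark_reads[bed.stem] = reads
        truth = pd.DataFrame(payload["truth"])
        return cls(
            config=config, genes=genes, chrom_lengths=chrom_lengths, rna=rna,
            chip=chip, tf_reads=tf_reads, tf_samples=tf_samples,
            mark_reads=mark_reads, truth=truth,
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _tile_genes(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, int]]:
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    gaps = rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1, size=cfg.n_genes)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cursor = {c: 2500 for c in chroms}  # room for the 2 kb upstream flank
    rows = []
    for i in range(cfg.n_genes):
        chrom = chroms[i % cfg.n_chroms]
        start = cursor[chrom]
        end = start + int(lengths[i])
        rows.append([f"g{i:05d}", chrom, start, end, strands[i]])
        cursor[chrom] = end + int(gaps[i])
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    chrom_lengths = {c: cursor[c] + 2500 for c in chroms}
    return genes, chrom_lengths


def _pick(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    if k > len(pool):
        raise ValueError("infeasible truth fractions: requested subset exceeds its pool")
    return rng.choice(pool, size=k, replace=False)


def _assign_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    idx = np.arange(n)
    n_primed = round(n * cfg.priming_fraction)
    n_bound = round(n * cfg.bound_fraction)
    n_me1 = round(n * cfg.me1_fraction)
    n_me3 = round(n * cfg.me3_fraction)
    n_induced = round(n * cfg.induced_fraction)
    n_repressed = round(n * cfg.repressed_fraction)
    if n_primed > min(n_bound, n_me1, n_me3, n_induced):
        raise ValueError(
            "infeasible fractions: primed genes must fit inside the bound, "
            "me1+, me3+ and induced sets"
        )
    primed = np.zeros(n, bool)
    primed[_pick(rng, idx, n_primed)] = True
    bound = primed.copy()
    bound[_pick(rng, idx[~bound], n_bound - n_primed)] = True
    me1 = primed.copy()
    me1[_pick(rng, idx[~me1], n_me1 - n_primed)] = True
    me3 = primed.copy()
    me3[_pick(rng, idx[~me3], n_me3 - n_primed)] = True
    induced = primed.copy()
    induced[_pick(rng, idx[~induced], n_induced - n_primed)] = True
    repressed = np.zeros(n, bool)
    repressed[_pick(rng, idx[~induced], n_repressed)] = True
    me_class = np.where(
        me1, np.where(me3, "me1+me3+", "me1+me3-"), np.where(me3, "me1-me3+", "me1-me3-")
    )
    return pd.DataFrame(
        {
            "primed": primed, "bound": bound, "induced": induced,
            "repressed": repressed, "me1_pos": me1, "me3_pos": me3,
            "me_class": me_class,
        }
    )


def _gamma_factors(cfg: SimConfig, rng: np.random.Generator, n_reps: int) -> np.ndarray:
    """Unit-mean gamma factors, (genes x replicate index), shared across conditions."""
    if cfg.nb_dispersion == 0:
        return np.ones((cfg.n_genes, n_reps))
    shape = 1.0 / cfg.nb_dispersion
    return rng.gamma(shape, scale=cfg.nb_dispersion, size=(cfg.n_genes, n_reps))


def _rna_multiplier(cfg: SimConfig, truth: pd.DataFrame, c0: np.ndarray,
                    genotype: str, stage: str) -> np.ndarray:
    mult = np.ones(cfg.n_genes)
    if stage == "C0":
        return c0
    if stage in ("C14S1", "C14S7"):
        fc = np.where(truth["induced"], cfg.induction_fc, 1.0)
        if genotype == "mutant":
            fc = np.where(truth["primed"], cfg.induction_fc * cfg.attenuation, fc)
        fc = np.where(truth["repressed"], 1.0 / cfg.induction_fc, fc)
        mult = fc
    return mult


def _mark_multiplier(cfg: SimConfig, truth: pd.DataFrame, gains: dict[str, np.ndarray],
                     assay: str, genotype: str, stage: str) -> np.ndarray:
    mult = np.ones(cfg.n_genes)
    if stage in ("C14", "C14S1") and assay in gains:
        mult = gains[assay].copy()  # callus-formation gain, maintained through S1
        if assay == "H3K4me2" and genotype == "mutant":
            # the mutant's failed removal: elevation at C14 carried to C14S1
            mult = mult * np.where(truth["primed"], cfg.me2_effect, 1.0)
    return mult


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate annotation, truth labels, count matrices and TF read tracks."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes, chrom_lengths = _tile_genes(cfg, rng)
    truth = _assign_truth(cfg, rng)
    truth.insert(0, "gene_id", genes["gene_id"])

    n = cfg.n_genes
    rna_base = cfg.mean_count * rng.lognormal(0.0, cfg.baseline_log_sd, n)
    mark_base = {
        "H3": cfg.mean_count * rng.lognormal(0.0, 0.2, n),
        "H3K4me1": cfg.mean_count
        * np.where(truth["me1_pos"], 1.7, 0.08)
        * rng.lognormal(0.0, cfg.mark_log_sd, n),
        "H3K4me2": cfg.mean_count * rng.lognormal(0.0, cfg.mark_log_sd, n),
        "H3K4me3": cfg.mean_count
        * np.where(truth["me3_pos"], 1.7, 0.08)
        * rng.lognormal(0.0, cfg.mark_log_sd, n),
        "H3K27me3": 0.5 * cfg.mean_count * rng.lognormal(0.0, cfg.mark_log_sd, n),
    }
    # per-gene stage gains during callus formation, shared between genotypes;
    # the me2 gain spread is wide enough that genotype-vs-genotype scatters of
    # the stage delta reproduce the high correlations real replicates show
    gains = {
        "H3K4me2": rng.lognormal(np.log(cfg.me2_callus_gain), 0.5, n),
        "H3K4me1": rng.lognormal(np.log(1.2), 0.2, n),
        "H3K4me3": rng.lognormal(np.log(1.2), 0.2, n),
    }
    c0_expr = rng.lognormal(0.0, 0.3, n)

    regions = genic_regions(genes, chrom_lengths=chrom_lengths)
    unit_rna = pd.Series((genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"])
    unit_chip = pd.Series(
        (regions["end"] - regions["start"]).to_numpy(), index=genes["gene_id"]
    )

    # RNA counts: genotypes x stages x triplicates
    u_rna = _gamma_factors(cfg, rng, cfg.rna_replicates)
    rna_cols, rna_samples = {}, []
    for genotype in ("WT", "mutant"):
        for stage in RNA_STAGES:
            mult = _rna_multiplier(cfg, truth, c0_expr, genotype, stage)
            for k in range(cfg.rna_replicates):
                counts = rng.poisson(rna_base * mult * u_rna[:, k])
                sid = make_sample_id(genotype, stage, "RNA", k + 1)
                rna_cols[sid] = counts
                rna_samples.append((sid, genotype, stage, "RNA", k + 1))

    # Mark ChIP counts: assays x genotypes x stages x duplicates
    u_mark = {a: _gamma_factors(cfg, rng, cfg.chip_replicates) for a in MARK_ASSAYS}
    chip_cols, chip_samples = {}, []
    for assay in MARK_ASSAYS:
        for genotype in ("WT", "mutant"):
            for stage in CHIP_STAGES:
                mult = _mark_multiplier(cfg, truth, gains, assay, genotype, stage)
                for k in range(cfg.chip_replicates):
                    counts = rng.poisson(mark_base[assay] * mult * u_mark[assay][:, k])
                    sid = make_sample_id(genotype, stage, assay, k + 1)
                    chip_cols[sid] = counts
                    chip_samples.append((sid, genotype, stage, assay, k + 1))

    # TF ChIP + control at C14 (bound genes enriched, center-to-3' skew)
    # TF ChIP is modelled as a genome-uniform input-like background plus
    # signal reads concentrated in bound-gene bodies (skewed toward the 3'
    # half); the control track is the same background without signal.  TF
    # tracks carry Poisson sampling noise only: the enrichment caller, like
    # its field-standard counterparts, models technical counting noise.
    tf_reads, tf_samples = {}, []
    n_background = cfg.tf_mean_count * cfg.n_genes
    extra_mean = (cfg.binding_enrichment - 1.0) * cfg.tf_mean_count * truth["bound"].to_numpy()
    for k in range(cfg.chip_replicates):
        t_extra = rng.poisson(extra_mean)
        sid_t = make_sample_id("WT", "C14", "TF-ChIP", k + 1)
        sid_c = make_sample_id("WT", "C14", "TF-control", k + 1)
        signal = _place_reads(
            cfg, rng, genes, t_extra, skew=cfg.binding_skew, skew_mask=truth["bound"].to_numpy()
        )
        t_bg = _uniform_reads(cfg, rng, chrom_lengths, rng.poisson(n_background))
        tf_reads[sid_t] = (
            pd.concat([signal, t_bg], ignore_index=True)
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )
        tf_reads[sid_c] = _uniform_reads(cfg, rng, chrom_lengths, rng.poisson(n_background))
        tf_samples.append(
            SampleDescriptor(sid_t, "WT", "C14", "TF-ChIP", k + 1, max(len(tf_reads[sid_t]), 1))
        )
        tf_samples.append(
            SampleDescriptor(sid_c, "WT", "C14", "TF-control", k + 1, max(len(tf_reads[sid_c]), 1))
        )

    mark_reads: dict[str, pd.DataFrame] = {}
    if cfg.emit_mark_reads:
        for sid, _, _, _, _ in chip_samples:
            mark_reads[sid] = _place_reads(cfg, rng, genes, chip_cols[sid])

    # Library sizes model matched effective sequencing depth: every library of
    # an assay is assigned the assay's expected baseline total, so RPM/RPKM
    # ratios are free of composition renormalisation (the scaled-down gene
    # universe would otherwise let the injected effects shift every library
    # total by ~10-20%, an artifact genome-scale data does not show at this
    # size).  Samples backed by emitted read files instead record the actual
    # number of reads, keeping the sample sheet consistent with the BED files.
    depth = {"RNA": int(round(rna_base.sum()))}
    depth.update({a: int(round(mark_base[a].sum())) for a in MARK_ASSAYS})

    def build_matrix(cols, sample_info, units):
        df = pd.DataFrame(cols, index=genes["gene_id"])
        samples = []
        for sid, g, st, a, r in sample_info:
            if cfg.emit_mark_reads and a in MARK_ASSAYS:
                lib = int(max(df[sid].sum(), 1))
            else:
                lib = depth[a]
            samples.append(SampleDescriptor(sid, g, st, a, r, lib))
        return CountMatrix(df, samples, units)

    rna_cm = build_matrix(rna_cols, rna_samples, unit_rna)
    chip_cm = build_matrix(chip_cols, chip_samples, unit_chip)

    truth = truth.assign(rna_base=rna_base, me2_base=mark_base["H3K4me2"])
    return SimulatedDataset(
        config=cfg, genes=genes, chrom_lengths=chrom_lengths, rna=rna_cm,
        chip=chip_cm, tf_reads=tf_reads, tf_samples=tf_samples,
        mark_reads=mark_reads, truth=truth,
    )


def _place_reads(
    cfg: SimConfig,
    rng: np.random.Generator,
    genes: pd.DataFrame,
    counts: np.ndarray,
    skew: float = 0.0,
    skew_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Place ``counts[g]`` reads of the emitted fragment length inside each gene body.

    With ``skew`` and a mask, that fraction of a masked gene's reads is placed
    uniformly in the 3' half of the body (strand-aware); the rest, and all
    reads of unmasked genes, are uniform over the whole body.
    """
    frag = cfg.fragment_length_emitted
    idx = np.repeat(np.arange(len(genes)), counts)
    if len(idx) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    g_start = genes["start"].to_numpy()[idx]
    g_end = genes["end"].to_numpy()[idx]
    g_plus = (genes["strand"].to_numpy() == "+")[idx]
    lo = g_start.copy()
    hi = np.maximum(g_end - frag, g_start + 1)
    if skew > 0 and skew_mask is not None:
        mid = (g_start + g_end) // 2
        in_skew = skew_mask[idx] & (rng.random(len(idx)) < skew)
        # 3' half of the body: right half for +, left half for - genes
        lo = np.where(in_skew & g_plus, mid, lo)
        hi = np.where(in_skew & g_plus, np.maximum(g_end - frag, mid + 1), hi)
        hi = np.where(in_skew & ~g_plus, np.maximum(mid - frag, g_start + 1), hi)
    starts = lo + (rng.random(len(idx)) * (hi - lo)).astype(np.int64)
    strands = np.where(rng.random(len(idx)) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy()[idx],
            "start": starts,
            "end": starts + frag,
            "strand": strands,
        }
    )


def _uniform_reads(
    cfg: SimConfig, rng: np.random.Generator, chrom_lengths: dict[str, int], n: int
) -> pd.DataFrame:
    """Genome-uniform background reads (input-like chromatin)."""
    frag = cfg.fragment_length_emitted
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] - frag for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    starts = (rng.random(n) * lengths[which]).astype(np.int64)
    df = pd.DataFrame(
        {
            "chrom": np.array(chroms)[which],
            "start": starts,
            "end": starts + frag,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def null_dataset(config: SimConfig) -> SimulatedDataset:
    """Dataset with no priming and genotypes statistically exchangeable."""
    cfg = dataclasses.replace(
        config, priming_fraction=0.0, me2_effect=1.0, attenuation=1.0
    )
    return simulate_dataset(cfg)
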