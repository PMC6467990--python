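"""Sample metadata and count-matrix containers.

The whole pipeline operates on a single genes x samples integer count matrix
(RNA-seq read counts per gene, or ChIP-seq read counts per genic region)
annotated with a sample sheet.  Normalized views (RPM, RPKM, row z-scores, ...)
are thin wrappers around a :class:`pandas.DataFrame` that remember the scale
and any pseudocount that was applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "mutant")
STAGES = ("C0", "C14", "C14S1", "C14S7")
ASSAYS = ("RNA", "H3", "H3K4me1", "H3K4me2", "H3K4me3", "H3K27me3", "TF-ChIP", "TF-control")

SAMPLE_SHEET_COLUMNS = ["sample_id", "genotype", "stage", "assay", "replicate", "library_size"]


@dataclass(frozen=True)
class SampleDescriptor:
    """One sequencing library: genotype x stage x assay x replicate."""

    sample_id: str
    genotype: str
    stage: str
    assay: str
    replicate: int
    library_size: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if self.library_size <= 0:
            raise ValueError(f"library_size must be > 0 for sample {self.sample_id!r}")


def make_sample_id(genotype: str, stage: str, assay: str, replicate: int) -> str:
    return f"{genotype}_{stage}_{assay}_rep{replicate}"


class CountMatrix:
    """Genes x samples non-negative integer counts plus sample descriptors.

    ``counts`` is indexed by gene_id with one column per sample_id (in sample
    order); ``unit_lengths`` holds the genic-region length in bp used for RPKM.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: list[SampleDescriptor],
        unit_lengths: pd.Series,
    ) -> None:
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in sample list")
        keys = {(s.genotype, s.stage, s.assay, s.replicate) for s in samples}
        if len(keys) != len(samples):
            raise ValueError("duplicate (genotype, stage, assay, replicate) combination")
        if list(counts.columns) != sample_ids:
            raise ValueError("count columns do not match sample descriptors")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        unit_lengths = unit_lengths.reindex(counts.index)
        if unit_lengths.isna().any():
            missing = unit_lengths.index[unit_lengths.isna()].tolist()[:5]
            raise ValueError(f"unit_lengths missing for genes {missing}")
        if (unit_lengths <= 0).any():
            raise ValueError("unit_lengths must be > 0")
        self.counts = counts.astype(np.int64)
        self.samples = list(samples)
        self.unit_lengths = unit_lengths.astype(np.int64)

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def library_sizes(self) -> pd.Series:
        return pd.Series({s.sample_id: s.library_size for s in self.samples})

    def descriptor(self, sample_id: str) -> SampleDescriptor:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(
        self,
        genotype: str | None = None,
        stage: str | None = None,
        assay: str | None = None,
        replicate: int | None = None,
    ) -> "CountMatrix":
        """Subset samples by descriptor fields; gene axis is untouched."""
        keep = [
            s
            for s in self.samples
            if (genotype is None or s.genotype == genotype)
            and (stage is None or s.stage == stage)
            and (assay is None or s.assay == assay)
            and (replicate is None or s.replicate == replicate)
        ]
        if not keep:
            raise ValueError(
                f"no samples match genotype={genotype} stage={stage} "
                f"assay={assay} replicate={replicate}"
            )
        return CountMatrix(
            self.counts[[s.sample_id for s in keep]], keep, self.unit_lengths
        )

    def sorted_replicates(self, genotype: str, stage: str, assay: str) -> "CountMatrix":
        sub = self.select(genotype=genotype, stage=stage, assay=assay)
        order = sorted(sub.samples, key=lambda s: s.replicate)
        return CountMatrix(sub.counts[[s.sample_id for s in order]], order, sub.unit_lengths)

    # -- I/O ---------------------------------------------------------------
    def write(self, counts_path: str | Path, sheet_path: str | Path) -> None:
        write_counts_tsv(self.counts, self.unit_lengths, counts_path)
        write_sample_sheet(self.samples, sheet_path)

    @classmethod
    def read(cls, counts_path: str | Path, sheet_path: str | Path) -> "CountMatrix":
        counts, lengths = read_counts_tsv(counts_path)
        samples = read_sample_sheet(sheet_path)
        samples = [s for s in samples if s.sample_id in counts.columns]
        counts = counts[[s.sample_id for s in samples]]
        return cls(counts, samples, lengths)


@dataclass
class NormalizedMatrix:
    """A normalized view of a count matrix.

    ``pseudocount`` records the half-minimum offset if one was applied (0.0
    otherwise) so downstream ratio computations are auditable.
    """

    values: pd.DataFrame
    scale: str  # {RPM, RPKM, sqrtRPM, log2ratio, zscore}
    pseudocount: float = 0.0
    samples: list[SampleDescriptor] = field(default_factory=list)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "NormalizedMatrix":
        return replace(self, values=values, scale=scale or self.scale)


# ---------------------------------------------------------------------------
# TSV round-trips (counts keep a unit_length column next to gene_id)
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, unit_lengths: pd.Series, path: str | Path) -> None:
    out = counts.copy()
    out.insert(0, "unit_length", unit_lengths.reindex(counts.index))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("unit_length")
    return df, lengths


def write_sample_sheet(samples: list[SampleDescriptor], path: str | Path) -> None:
    rows = [
        [s.sample_id, s.genotype, s.stage, s.assay, s.replicate, s.library_size]
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleDescriptor]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleDescriptor(
            sample_id=str(r.sample_id),
            genotype=str(r.genotype),
            stage=str(r.stage),
            assay=str(r.assay),
            replicate=int(r.replicate),
            library_size=int(r.library_size),
        )
        for r in df.itertuples()
    ]
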