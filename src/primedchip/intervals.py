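"""Genomic intervals: annotation ingest, read extension, overlap counting,
and metagene positional profiles.

Coordinates are 0-based half-open throughout (BED convention); GFF3 input is
converted on ingest.  Genes, genic regions and reads are held as pandas
DataFrames (one row per record) with BED-like columns, which keeps the
vectorised interval arithmetic simple and lets every table round-trip through
plain BED6/TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
READ_COLUMNS = ["chrom", "start", "end", "strand"]

DEFAULT_FLANK = 2000  # bp each side of the gene body (the profiled genic region)
DEFAULT_FRAGMENT_LENGTH = 250  # bp; average insert size reads are extended to
DEFAULT_BODY_BINS = 100
DEFAULT_FLANK_BINS = 50


@dataclass(frozen=True)
class MetageneProfile:
    """Mean per-base signal in scaled bins: upstream flank, body 5'->3', downstream."""

    body_bins: int
    flank_bins: int
    values: np.ndarray
    n_genes: int
    signal_units: str  # {reads-per-base, RPM-per-base}

    def __post_init__(self) -> None:
        if len(self.values) != 2 * self.flank_bins + self.body_bins:
            raise ValueError("profile length != 2*flank_bins + body_bins")

    def to_frame(self) -> pd.DataFrame:
        classes = (
            ["up"] * self.flank_bins + ["body"] * self.body_bins + ["down"] * self.flank_bins
        )
        return pd.DataFrame(
            {"bin_index": np.arange(len(self.values)), "bin_class": classes, "value": self.values}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation ingest
# ---------------------------------------------------------------------------

def _validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    genes = genes.reset_index(drop=True)
    dup = genes["gene_id"][genes["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id: {dup.iloc[0]!r}")
    bad = genes[(genes["start"] < 0) | (genes["start"] >= genes["end"])]
    if len(bad):
        raise ValueError(
            f"invalid interval for gene {bad['gene_id'].iloc[0]!r}: "
            f"start={bad['start'].iloc[0]} end={bad['end'].iloc[0]}"
        )
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return genes


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation from GFF3 (``gene`` features) or BED6.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand in
    0-based half-open coordinates.  GFF3 1-based closed coordinates are
    converted; BED is taken verbatim.
    """
    path = Path(path)
    text = path.read_text()
    first_data = next(
        (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")), ""
    )
    if path.suffix.lower() in {".gff", ".gff3"} or len(first_data.split("\t")) == 9:
        return _read_gff3(path, text)
    return _read_bed_genes(path, text)


def _read_gff3(path: Path, text: str) -> pd.DataFrame:
    import gffutils

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"{path}:{lineno}: malformed GFF3 line (expected 9 fields)")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features(featuretype="gene"):
        rows.append([feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand])
    if not rows:
        raise ValueError(f"{path}: no 'gene' features found")
    return _validate_genes(pd.DataFrame(rows, columns=GENE_COLUMNS))


def _read_bed_genes(path: Path, text: str) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: malformed BED line (expected >= 6 fields)")
        try:
            rows.append([fields[3], fields[0], int(fields[1]), int(fields[2]), fields[5]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: empty annotation")
    return _validate_genes(pd.DataFrame(rows, columns=GENE_COLUMNS))


def genic_regions(
    genes: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Gene body +/- ``flank`` bp, clamped at 0 and at chromosome ends when known."""
    regions = genes.copy()
    regions["start"] = np.maximum(genes["start"] - flank, 0)
    regions["end"] = genes["end"] + flank
    if chrom_lengths:
        limit = genes["chrom"].map(chrom_lengths)
        if limit.notna().all():
            regions["end"] = np.minimum(regions["end"], limit.astype(np.int64))
    regions["flank"] = flank
    return regions


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def read_bed_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return df[READ_COLUMNS]


def write_bed_reads(reads: pd.DataFrame, path: str | Path) -> None:
    out = reads.copy()
    out.insert(3, "name", [f"read{i}" for i in range(len(out))])
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


def extend_reads(
    reads: pd.DataFrame,
    target_length: int = DEFAULT_FRAGMENT_LENGTH,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Fix each read's 5' end and resize it to ``target_length`` toward its 3' end.

    Plus-strand reads get end = start + L; minus-strand reads get
    start = end - L (clamped at 0, and at the chromosome end when lengths are
    supplied).  Reads already longer than L are truncated from the 5' end, so
    all fragments come out the same length; the operation is idempotent.
    """
    if target_length <= 0:
        raise ValueError("target_length must be > 0")
    out = reads.copy()
    plus = out["strand"].to_numpy() == "+"
    start = out["start"].to_numpy(copy=True)
    end = out["end"].to_numpy(copy=True)
    end[plus] = start[plus] + target_length
    start[~plus] = np.maximum(end[~plus] - target_length, 0)
    if chrom_lengths:
        limit = out["chrom"].map(chrom_lengths).to_numpy()
        end = np.minimum(end, limit)
    out["start"] = start
    out["end"] = end
    return out


def count_overlaps(reads: pd.DataFrame, units: pd.DataFrame) -> pd.Series:
    """Reads sharing >= 1 bp with each annotation unit (multi-assignment).

    A read overlapping k units contributes 1 to each.  Returns an int Series
    indexed by the units' gene_id.
    """
    counts = np.zeros(len(units), dtype=np.int64)
    if len(reads):
        for chrom, r in reads.groupby("chrom", sort=False):
            mask = (units["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            starts = np.sort(r["start"].to_numpy())
            ends = np.sort(r["end"].to_numpy())
            u_start = units.loc[mask, "start"].to_numpy()
            u_end = units.loc[mask, "end"].to_numpy()
            # overlap iff read.start < unit.end and read.end > unit.start;
            # the two excluded sets are disjoint for non-empty reads
            n_start_before_end = np.searchsorted(starts, u_end, side="left")
            n_end_before_start = np.searchsorted(ends, u_start, side="right")
            counts[mask] = n_start_before_end - n_end_before_start
    return pd.Series(counts, index=pd.Index(units["gene_id"], name="gene_id"))


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

def _coverage_arrays(reads: pd.DataFrame, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base coverage per chromosome via difference arrays."""
    cov = {}
    for chrom, length in chrom_lengths.items():
        diff = np.zeros(length + 1, dtype=np.float64)
        r = reads[reads["chrom"] == chrom]
        if len(r):
            starts = np.clip(r["start"].to_numpy(), 0, length)
            ends = np.clip(r["end"].to_numpy(), 0, length)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
        cov[chrom] = np.cumsum(diff)[:length]
    return cov


def _rebin(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean per-base signal in ``n_bins`` equal-width bins.

    Bin means are taken from the cumulative coverage with linear interpolation
    at fractional edges, which reduces to exact block means for integer-width
    bins and to per-base linear interpolation when the segment is shorter than
    the bin grid.
    """
    m = len(values)
    if m == 0:
        return np.zeros(n_bins)
    cum = np.concatenate([[0.0], np.cumsum(values)])
    edges = np.linspace(0.0, m, n_bins + 1)
    ce = np.interp(edges, np.arange(m + 1), cum)
    return np.diff(ce) / (m / n_bins)


def metagene_profile(
    reads: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bins: int = DEFAULT_FLANK_BINS,
    library_size: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> MetageneProfile:
    """Orientation-normalised mean coverage over gene body +/- flank.

    Reads should already be extended to fragment length.  The body is rescaled
    to ``body_bins`` bins and each flank to ``flank_bins`` bins; minus-strand
    genes are reversed so bin order runs 5'->3'.  With ``library_size`` the
    signal is reported as RPM-per-base, otherwise reads-per-base.
    """
    if len(genes) == 0:
        raise ValueError("metagene_profile requires at least one gene")
    if body_bins < 1 or flank_bins < 1:
        raise ValueError("body_bins and flank_bins must be >= 1")
    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom in set(genes["chrom"]):
            g_end = genes.loc[genes["chrom"] == chrom, "end"].max() + flank
            r = reads[reads["chrom"] == chrom]
            r_end = r["end"].max() if len(r) else 0
            chrom_lengths[chrom] = int(max(g_end, r_end))
    cov = _coverage_arrays(reads, chrom_lengths)
    total = np.zeros(2 * flank_bins + body_bins)
    for g in genes.itertuples():
        c = cov[g.chrom]
        length = len(c)
        up_lo, up_hi = max(0, g.start - flank), g.start
        dn_lo, dn_hi = g.end, min(length, g.end + flank)
        left = _rebin(c[up_lo:up_hi], flank_bins)
        body = _rebin(c[g.start:g.end], body_bins)
        right = _rebin(c[dn_lo:dn_hi], flank_bins)
        prof = np.concatenate([left, body, right])
        if g.strand == "-":
            prof = prof[::-1]
        total += prof
    values = total / len(genes)
    units = "reads-per-base"
    if library_size is not None:
        if library_size <= 0:
            raise ValueError("library_size must be > 0")
        values = values * 1e6 / library_size
        units = "RPM-per-base"
    return MetageneProfile(
        body_bins=body_bins, flank_bins=flank_bins, values=values,
        n_genes=len(genes), signal_units=units,
    )
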