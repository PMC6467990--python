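#!/usr/bin/env python
"""Step 8: positional TF profile over bound genes.

Scaled metagene of the extended TF reads across gene body +/- 2 kb; the TF
signal should concentrate from the gene-body center toward the 3' end."""

import argparse
from pathlib import Path

from primedchip.intervals import extend_reads, metagene_profile
from primedchip.simulate import SimulatedDataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    ds = SimulatedDataset.load(args.outdir / "sim")
    truth = ds.truth.set_index("gene_id")
    bound = ds.genes[ds.genes["gene_id"].isin(truth.index[truth["bound"]])]
    sid = "WT_C14_TF-ChIP_rep1"
    reads = extend_reads(ds.tf_reads[sid], 250, ds.chrom_lengths)
    prof = metagene_profile(
        reads, bound, flank=2000, body_bins=100, flank_bins=50,
        library_size=len(reads), chrom_lengths=ds.chrom_lengths,
    )
    out = args.outdir / "report" / "tf_metagene_bound.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    prof.write(out)
    body = prof.values[50:150]
    print(f"metagene over {prof.n_genes} bound genes ({prof.signal_units}) -> {out}")
    print(
        f"body 5'-half mean {body[:50].mean():.4f}, 3'-half mean {body[50:].mean():.4f} "
        f"(ratio {body[50:].mean() / body[:50].mean():.2f})"
    )


if __name__ == "__main__":
    main()
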