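#!/usr/bin/env python
"""Step 5: hyper-H3K4me2 genes in the mutant at C14.

Paired mutant-vs-WT test per genic region; the hyper set requires a
pseudocounted RPM ratio > 1.5 at BH q < 0.01."""

import argparse
from pathlib import Path

from primedchip.workflow import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    run = RunConfig(outdir=args.outdir, seed=args.seed)
    hyper = run_pipeline(run, "hyper")
    print(f"hyper-H3K4me2 genes at C14: {len(hyper)}")


if __name__ == "__main__":
    main()
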