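#!/usr/bin/env python
"""Step 3: call TF-bound genes from the ChIP/control pair.

Windowed local-lambda Poisson enrichment, BH-adjusted genome-wide, peaks at
q < 0.1, assigned to genes through genic regions."""

import argparse
import json
from pathlib import Path

import pandas as pd

from primedchip.workflow import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    run = RunConfig(outdir=args.outdir, seed=args.seed)
    bound = run_pipeline(run, "bind")
    truth = pd.DataFrame(
        json.loads((args.outdir / "sim" / "truth.json").read_text())["truth"]
    ).set_index("gene_id")
    true_bound = set(truth.index[truth["bound"]])
    tp = len(bound & true_bound)
    print(f"bound genes called: {len(bound)} (truth: {len(true_bound)})")
    print(
        f"sensitivity {tp / len(true_bound):.3f}, precision {tp / max(len(bound), 1):.3f}"
    )


if __name__ == "__main__":
    main()
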