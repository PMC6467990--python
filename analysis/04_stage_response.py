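#!/usr/bin/env python
"""Step 4: wild-type stage-response gene sets.

Paired tests of C14 vs C14S1 and C14 vs C14S7 expression define the up- and
down-regulated sets (UGs/DGs) at FC > 1.25 / < 0.8 and BH q < 0.01."""

import argparse
from pathlib import Path

from primedchip.workflow import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    run = RunConfig(outdir=args.outdir, seed=args.seed)
    sets = run_pipeline(run, "respond")
    for name in ("UGs_S1", "DGs_S1", "UGs_S7", "DGs_S7"):
        print(f"{name}: {len(sets[name])} genes")


if __name__ == "__main__":
    main()
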