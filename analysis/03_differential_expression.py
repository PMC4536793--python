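#!/usr/bin/env python
"""Loess-normalize the mutant-vs-WT arrays and call differential
expression with the one-class SAM permutation FDR (q < 0.005).

Reports power and precision against the planted fold-changes.
"""

import argparse
import json
from pathlib import Path

from pombechip.pipeline import PipelineConfig, run_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--outdir", default="results/diffexpr")
    args = ap.parse_args()
    sim = Path(args.simdir)
    run_stage(
        "diffexpr",
        PipelineConfig(
            outdir=args.outdir,
            seed=args.seed,
            expr_matrix=str(sim / "expr_matrix.tsv"),
            intensities=str(sim / "intensities.tsv"),
        ),
    )
    out = Path(args.outdir)
    called = set((out / "de_up.txt").read_text().split()) | set(
        (out / "de_down.txt").read_text().split()
    )
    truth = set(json.loads((sim / "ground_truth.json").read_text())["de_log2fc"])
    tp = len(called & truth)
    print(f"called {len(called)} DE genes; planted {len(truth)}")
    print(f"power {tp / len(truth):.3f}, precision {tp / max(len(called), 1):.3f}")


if __name__ == "__main__":
    main()
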