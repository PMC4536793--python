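#!/usr/bin/env python
"""ChIP-qPCR relative quantification by the comparative Ct method.

Computes 2^-ddCt per replicate from the simulated Ct table (target
locus vs reference locus, IP vs input) and summarizes replicates by
geometric mean.
"""

import argparse
from pathlib import Path

from pombechip.pipeline import PipelineConfig, run_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--outdir", default="results/qpcr")
    args = ap.parse_args()
    run_stage(
        "qpcr",
        PipelineConfig(
            outdir=args.outdir, ct_table=str(Path(args.simdir) / "ct_table.tsv")
        ),
    )
    print((Path(args.outdir) / "qpcr_summary.tsv").read_text())


if __name__ == "__main__":
    main()
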