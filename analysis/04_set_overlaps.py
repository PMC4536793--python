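#!/usr/bin/env python
"""Venn-style overlap statistics between the called RIP targets and the
called differentially expressed genes.

For each pair of lists: observed overlap, the expected overlap of
random lists of the same sizes (|A||B|/N), and the one-sided Fisher
exact p-value over the array universe.
"""

import argparse
from pathlib import Path

from pombechip.pipeline import PipelineConfig, run_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--ripdir", default="results/ripchip")
    ap.add_argument("--dedir", default="results/diffexpr")
    ap.add_argument("--outdir", default="results/overlap")
    args = ap.parse_args()
    sim, out = Path(args.simdir), Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    targets = [
        line.split("\t")[0]
        for line in (Path(args.ripdir) / "targets.tsv").read_text().splitlines()[2:]
    ]
    (out / "targets.txt").write_text("".join(f"{g}\n" for g in targets))
    universe = [
        line.split("\t")[0]
        for line in (sim / "rip_matrix.tsv").read_text().splitlines()[1:]
    ]
    (out / "universe.txt").write_text("".join(f"{g}\n" for g in universe))

    run_stage(
        "overlap",
        PipelineConfig(
            outdir=str(out),
            universe=str(out / "universe.txt"),
            gene_lists={
                "rip_targets": str(out / "targets.txt"),
                "de_up": str(Path(args.dedir) / "de_up.txt"),
                "de_down": str(Path(args.dedir) / "de_down.txt"),
            },
        ),
    )
    print((out / "overlap.tsv").read_text())


if __name__ == "__main__":
    main()
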