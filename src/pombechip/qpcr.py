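"""Relative quantification of ChIP-qPCR by the comparative Ct method.

A quantification compares a target locus (e.g. the mei4 DSR region)
against a reference locus (e.g. cdc2) in both the immunoprecipitated
(IP) and input fractions:

    ddCt = (Ct_target_IP - Ct_ref_IP) - (Ct_target_INPUT - Ct_ref_INPUT)
    ratio = 2 ** (-ddCt)

PCR efficiency is taken as exactly 2 per cycle, as the formula assumes.
An alternative sign convention, in which the two deltas are summed
rather than differenced, is available behind ``literal_sign=True`` for
comparison; the comparative (difference-of-differences) form is the
default. Replicate ratios are aggregated by geometric mean, ratios
being log-scale quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENES = ("target", "reference")
FRACTIONS = ("IP", "INPUT")


@dataclass(frozen=True)
class CtMeasurement:
    """One well: gene role x fraction x replicate -> critical cycle."""

    gene: str  # "target" or "reference"
    fraction: str  # "IP" or "INPUT"
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"gene must be one of {GENES}, got {self.gene!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if not self.ct > 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")


#: the four cells a complete quantification requires
QUARTET_CELLS = tuple((g, f) for g in GENES for f in FRACTIONS)


def delta_delta_ct(
    quartet: dict[tuple[str, str], float], literal_sign: bool = False
) -> float:
    """2^-ddCt ratio from a complete {(gene, fraction): Ct} quartet.

    Raises KeyError naming the missing cell if the quartet is incomplete.
    ``literal_sign=True`` switches to the summed-deltas exponent
    2^(-(dIP) - (dINPUT)).
    """
    missing = [cell for cell in QUARTET_CELLS if cell not in quartet]
    if missing:
        raise KeyError(f"incomplete quartet; missing cells: {missing}")
    d_ip = quartet[("target", "IP")] - quartet[("reference", "IP")]
    d_input = quartet[("target", "INPUT")] - quartet[("reference", "INPUT")]
    exponent = -(d_ip + d_input) if literal_sign else -(d_ip - d_input)
    return float(2.0 ** exponent)


def quartets_from_measurements(
    measurements: list[CtMeasurement],
) -> dict[int, dict[tuple[str, str], float]]:
    """Group measurements into per-replicate quartets (possibly partial)."""
    by_rep: dict[int, dict[tuple[str, str], float]] = {}
    for m in measurements:
        cell = (m.gene, m.fraction)
        rep = by_rep.setdefault(m.replicate, {})
        if cell in rep:
            raise ValueError(f"replicate {m.replicate}: duplicate cell {cell}")
        rep[cell] = m.ct
    return by_rep


@dataclass
class DdctSummary:
    ratios: dict[int, float]  # replicate -> 2^-ddCt ratio
    mean_ratio: float  # geometric mean
    sd_log2: float | None  # SD of log2 ratios; None with a single replicate

    @property
    def n(self) -> int:
        return len(self.ratios)


def ddct_summary(
    measurements: list[CtMeasurement], literal_sign: bool = False
) -> DdctSummary:
    """Per-replicate ratios, their geometric mean, and the log2-scale SD.

    Replicates with an incomplete quartet are skipped; at least one
    complete quartet is required.
    """
    by_rep = quartets_from_measurements(measurements)
    ratios = {
        rep: delta_delta_ct(q, literal_sign=literal_sign)
        for rep, q in sorted(by_rep.items())
        if all(cell in q for cell in QUARTET_CELLS)
    }
    if not ratios:
        raise ValueError("no complete (gene x fraction) quartet among the measurements")
    logs = np.log2(list(ratios.values()))
    mean_ratio = float(2.0 ** np.mean(logs))
    sd = float(np.std(logs, ddof=1)) if len(logs) > 1 else None
    return DdctSummary(ratios=ratios, mean_ratio=mean_ratio, sd_log2=sd)


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """TSV with columns gene, fraction, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "fraction", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    return [
        CtMeasurement(
            gene=row.gene, fraction=row.fraction, ct=float(row.ct), replicate=int(row.replicate)
        )
        for row in df.itertuples()
    ]


def write_ct_table(measurements: list[CtMeasurement], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\tfraction\treplicate\tct\n")
        for m in measurements:
            fh.write(f"{m.gene}\t{m.fraction}\t{m.replicate}\t{m.ct:.4f}\n")
    return path


def write_summary(summary: DdctSummary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("replicate\tratio\n")
        for rep, r in summary.ratios.items():
            fh.write(f"{rep}\t{r:.6g}\n")
        sd = "" if summary.sd_log2 is None else f"{summary.sd_log2:.6g}"
        fh.write(f"geometric_mean\t{summary.mean_ratio:.6g}\n")
        fh.write(f"sd_log2\t{sd}\n")
    return path
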