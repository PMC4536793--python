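"""The probe/gene x replicate log2-ratio container shared by the RIP-chip
and expression stages.

A thin wrapper around a pandas DataFrame (rows = gene/probe ids, columns =
replicate sample ids, values = log2 two-channel ratios, NaN = missing)
carrying the channel semantics: ``rip`` for IP-vs-total enrichments,
``expression`` for mutant-vs-wild-type ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNEL_SEMANTICS = ("rip", "expression")


@dataclass
class EnrichmentMatrix:
    values: pd.DataFrame
    channel: str = "rip"

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_SEMANTICS:
            raise ValueError(f"channel must be one of {CHANNEL_SEMANTICS}, got {self.channel!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups[:5]}")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "EnrichmentMatrix":
        return EnrichmentMatrix(values=values, channel=self.channel)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="gene_id", na_rep="")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, channel: str = "rip") -> "EnrichmentMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, channel=channel)


def require_min_finite(values: pd.DataFrame, min_finite: int = 2) -> None:
    """Raise if any column has fewer than ``min_finite`` non-missing cells."""
    counts = values.notna().sum(axis=0)
    bad = counts[counts < min_finite]
    if len(bad):
        raise ValueError(
            f"columns with fewer than {min_finite} non-missing values: "
            f"{list(bad.index)}"
        )


def detected_filter(
    matrix: EnrichmentMatrix,
    max_na_fraction: float = 0.5,
    min_intensity: float | None = None,
    intensities: pd.DataFrame | None = None,
) -> EnrichmentMatrix:
    """Drop rows that fail detection: too many missing cells, or (when an
    intensity table is given) mean intensity below ``min_intensity``.

    The upstream 'detected RNAs' criterion is not pinned down by the study
    design, so both knobs are explicit configuration.
    """
    keep = matrix.values.isna().mean(axis=1) <= max_na_fraction
    if min_intensity is not None:
        if intensities is None:
            raise ValueError("min_intensity filter requires an intensity table")
        keep &= intensities.reindex(matrix.values.index).mean(axis=1) >= min_intensity
    return matrix.with_values(matrix.values.loc[keep])
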