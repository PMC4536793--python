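"""RIP-chip target calling.

The procedure: log2(IP/total) enrichments per array are mean-centred, a
per-array z-score is computed, and a transcript is called a target when
its z-score exceeds 2.5 in at least k of n biological replicates (2-of-2
for duplicated experiments, 2-of-3 for triplicated ones).

Centring, the SD and the z-score are all per array (per column): each
hybridization has its own scale, and the replicate rule then asks for
reproducibility across arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pombechip.matrix import EnrichmentMatrix, require_min_finite

DEFAULT_Z_THRESHOLD = 2.5


@dataclass
class TargetCallSet:
    """Genes passing the z-score replicate-consistency rule."""

    called_ids: list[str]
    zscores: pd.DataFrame  # gene x replicate
    threshold: float
    rule: tuple[int, int]  # (k, n)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.called_ids)

    def __len__(self) -> int:
        return len(self.called_ids)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        k, n = self.rule
        with open(path, "w") as fh:
            fh.write(f"# z_threshold={self.threshold}\trule={k}-of-{n}\n")
            fh.write("gene_id\t" + "\t".join(f"z_{c}" for c in self.zscores.columns) + "\n")
            for gid in self.called_ids:
                zs = "\t".join(f"{z:.4f}" for z in self.zscores.loc[gid])
                fh.write(f"{gid}\t{zs}\n")
        return path


def mean_centre(matrix: EnrichmentMatrix) -> EnrichmentMatrix:
    """Subtract each column's mean over its non-missing cells.

    Idempotent; missing cells stay missing. Columns with < 2 non-missing
    values are rejected.
    """
    require_min_finite(matrix.values, 2)
    centred = matrix.values - matrix.values.mean(axis=0, skipna=True)
    return matrix.with_values(centred)


def zscores(matrix: EnrichmentMatrix) -> pd.DataFrame:
    """Per-column z-scores: (value - column mean) / column sample SD.

    Uses the n-1 (sample) SD. A zero-SD column yields all-zero z-scores
    rather than infinities.
    """
    require_min_finite(matrix.values, 2)
    centred = matrix.values - matrix.values.mean(axis=0, skipna=True)
    sd = matrix.values.std(axis=0, ddof=1, skipna=True)
    sd = sd.where(sd > 0, other=np.inf)  # zero-SD column -> z == 0
    z = centred / sd
    return z.where(matrix.values.notna())


def call_targets(
    z: pd.DataFrame,
    threshold: float = DEFAULT_Z_THRESHOLD,
    rule: tuple[int, int] | None = None,
) -> TargetCallSet:
    """Apply the k-of-n replicate rule to a gene x replicate z table.

    ``rule`` defaults to (2, n) with n the number of replicate columns,
    matching the 2-of-2 / 2-of-3 usage. "Above threshold" is strict.
    Genes with a missing z in some replicate are evaluated on the
    remaining replicates against the same k.
    """
    n_cols = z.shape[1]
    if rule is None:
        rule = (min(2, n_cols), n_cols)
    k, n = rule
    if not (1 <= k <= n):
        raise ValueError(f"require 1 <= k <= n, got rule {rule}")
    if n != n_cols:
        raise ValueError(f"rule n={n} but z table has {n_cols} replicate columns")
    n_passing = (z > threshold).sum(axis=1)
    called = z.index[n_passing >= k].tolist()
    return TargetCallSet(called_ids=called, zscores=z, threshold=threshold, rule=rule)


def relative_enrichment(
    matrix: EnrichmentMatrix,
    reference_id: str,
    query_ids: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """log2 enrichment of each query gene minus that of a reference gene.

    Used to display per-target enrichments normalized to a housekeeping
    reference (e.g. actin) alongside the median over queries.

    Returns (per-gene x replicate relative enrichments, per-replicate
    median over the queries).
    """
    if reference_id not in matrix.values.index:
        raise KeyError(f"reference {reference_id!r} not in matrix")
    missing = [q for q in query_ids if q not in matrix.values.index]
    if missing:
        raise KeyError(f"query ids not in matrix: {missing}")
    rel = matrix.values.loc[query_ids] - matrix.values.loc[reference_id]
    return rel, rel.median(axis=0)
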