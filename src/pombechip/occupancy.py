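"""ChIP-seq feature-level quantification and heterochromatin calls.

The quantification chain mirrors the standard histone-normalized
occupancy analysis: reads are counted per annotated feature, converted
to RPKM (reads per kilobase of feature per million mapped reads), and
the H3K9me2 density is divided by the histone H3 density measured in
parallel, so that changes in nucleosome occupancy do not masquerade as
changes in methylation.

Downstream calls:

* ``detect_enriched`` — a feature is an enriched (heterochromatic)
  domain when its me2/H3 ratio exceeds ``enrichment_factor`` times the
  background (median ratio over non-heterochromatin features) in every
  replicate ("reproducible enrichment above background").
* ``compare_conditions`` — a feature is called reduced in a mutant when
  the mutant/wild-type ratio fold is at most 1/``reduction_factor`` in
  every replicate pairing; increases are called symmetrically. The H3
  RPKM is compared in parallel so that a methylation loss can be
  distinguished from a histone-occupancy loss.

Thresholds default to 2-fold; the underlying study reports calls as
"clear and reproducible" without printing numeric cut-offs, so both
factors are configuration and are echoed into output headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import pysam

from pombechip.annotation_io import FeatureCatalog, HETEROCHROMATIN_CLASSES

ANTIBODIES = ("H3", "H3K9me2", "ChpTAP", "input")
AssignBy = Literal["start", "midpoint"]


@dataclass(frozen=True)
class SampleKey:
    """Identifies one sequencing sample: antibody x condition x replicate."""

    antibody: str
    condition: str
    replicate: int = 1

    def __str__(self) -> str:
        return f"{self.antibody}:{self.condition}:{self.replicate}"

    @classmethod
    def parse(cls, s: str) -> "SampleKey":
        antibody, condition, rep = s.split(":")
        return cls(antibody, condition, int(rep))


@dataclass
class ReadSet:
    """Aligned reads of one sample, stored as per-chromosome start arrays.

    ``starts`` maps chrom -> int array of 0-based leftmost positions;
    ``read_length`` is uniform (reads are trimmed to a fixed length
    upstream). Strand is irrelevant to feature counting and not stored.
    """

    sample: SampleKey
    starts: dict[str, np.ndarray]
    read_length: int = 50

    @property
    def n_reads(self) -> int:
        return int(sum(len(v) for v in self.starts.values()))

    def to_bed(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom in self.starts:
                for i, s in enumerate(self.starts[chrom]):
                    fh.write(
                        f"{chrom}\t{s}\t{s + self.read_length}\t"
                        f"{self.sample}:{i}\t0\t+\n"
                    )
        return path


def read_bed_reads(path: str | Path, sample: SampleKey, read_length: int = 50) -> ReadSet:
    """Load aligned reads from a BED file (chrom, start, end used)."""
    starts: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            starts.setdefault(f[0], []).append(int(f[1]))
    return ReadSet(
        sample=sample,
        starts={c: np.asarray(v, dtype=np.int64) for c, v in starts.items()},
        read_length=read_length,
    )


def read_sam_reads(path: str | Path, sample: SampleKey, read_length: int = 50) -> ReadSet:
    """Load primary alignments from a SAM file.

    Secondary, supplementary and unmapped records are skipped, so each
    fragment contributes a single placement.
    """
    starts: dict[str, list[int]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            starts.setdefault(rec.reference_name, []).append(rec.reference_start)
    return ReadSet(
        sample=sample,
        starts={c: np.asarray(v, dtype=np.int64) for c, v in starts.items()},
        read_length=read_length,
    )


def count_reads(
    reads: ReadSet,
    catalog: FeatureCatalog,
    assign_by: AssignBy = "start",
) -> pd.Series:
    """Per-feature read counts using a single assignment point per read.

    A read is assigned to every feature whose half-open interval contains
    its assignment point (the leftmost position by default, the midpoint
    as an alternative); overlapping features each receive the read.
    Reads hitting no feature still count toward the library size.
    """
    known = set(catalog.chrom_sizes)
    unknown = [c for c in reads.starts if c not in known]
    if unknown:
        raise ValueError(f"reads on unknown chromosome(s): {sorted(unknown)}")
    points: dict[str, np.ndarray] = {}
    for chrom, s in reads.starts.items():
        p = s if assign_by == "start" else s + reads.read_length // 2
        points[chrom] = np.sort(p)
    counts = np.zeros(len(catalog.features), dtype=np.int64)
    for i, f in enumerate(catalog.features):
        p = points.get(f.chrom)
        if p is None:
            continue
        counts[i] = np.searchsorted(p, f.end, side="left") - np.searchsorted(
            p, f.start, side="left"
        )
    return pd.Series(counts, index=catalog.ids(), name=str(reads.sample))


def rpkm(
    counts: pd.Series | pd.DataFrame,
    catalog: FeatureCatalog,
    library_sizes: int | dict[str, int] | pd.Series,
) -> pd.Series | pd.DataFrame:
    """RPKM = count / (feature length in kb) / (library size in millions).

    The library size is the total number of aligned reads in the sample,
    not only the in-feature reads.
    """
    lengths = pd.Series(
        {f.feature_id: f.length for f in catalog.features}, dtype=float
    ).reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("zero-length feature in catalog")
    kb = lengths / 1000.0
    if isinstance(counts, pd.Series):
        lib = float(library_sizes) if np.isscalar(library_sizes) else float(
            library_sizes[counts.name]
        )
        if lib <= 0:
            raise ValueError("library size must be positive")
        return counts / kb / (lib / 1e6)
    libs = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(kb, axis=0).div(libs / 1e6, axis=1)


def h3_normalize(me2_rpkm: pd.Series, h3_rpkm: pd.Series) -> pd.Series:
    """me2/H3 ratio per feature; NaN (undefined, not zero) where H3 == 0."""
    h3 = h3_rpkm.reindex(me2_rpkm.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = me2_rpkm / h3.where(h3 > 0)
    return ratio


@dataclass
class OccupancyTable:
    """Feature-level quantification across samples.

    ``counts`` and ``rpkm`` are feature x sample (columns are stringified
    :class:`SampleKey`); ``ratios`` maps condition -> feature x replicate
    me2/H3 ratio table; ``library_sizes`` maps sample -> aligned reads.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    ratios: dict[str, pd.DataFrame]
    library_sizes: dict[str, int] = field(default_factory=dict)

    def h3_rpkm(self, condition: str) -> pd.DataFrame:
        cols = [
            c
            for c in self.rpkm.columns
            if SampleKey.parse(c).antibody == "H3"
            and SampleKey.parse(c).condition == condition
        ]
        return self.rpkm[cols]


def quantify(
    readsets: Iterable[ReadSet],
    catalog: FeatureCatalog,
    assign_by: AssignBy = "start",
) -> OccupancyTable:
    """Count, RPKM-normalize and H3-normalize a batch of samples.

    The me2/H3 ratio is formed per (condition, replicate): the H3K9me2
    RPKM of replicate r is divided by the H3 RPKM of the same condition
    and replicate.
    """
    counts = {}
    libs = {}
    keys: list[SampleKey] = []
    for rs in readsets:
        name = str(rs.sample)
        counts[name] = count_reads(rs, catalog, assign_by=assign_by)
        libs[name] = rs.n_reads
        keys.append(rs.sample)
    count_df = pd.DataFrame(counts)
    rpkm_df = rpkm(count_df, catalog, libs)

    ratios: dict[str, pd.DataFrame] = {}
    conditions = sorted({k.condition for k in keys})
    for cond in conditions:
        reps = sorted(
            {k.replicate for k in keys if k.condition == cond and k.antibody == "H3K9me2"}
        )
        cols = {}
        for r in reps:
            me2_key = str(SampleKey("H3K9me2", cond, r))
            h3_key = str(SampleKey("H3", cond, r))
            if me2_key in rpkm_df and h3_key in rpkm_df:
                cols[f"rep{r}"] = h3_normalize(rpkm_df[me2_key], rpkm_df[h3_key])
        if cols:
            ratios[cond] = pd.DataFrame(cols)
    return OccupancyTable(
        counts=count_df, rpkm=rpkm_df, ratios=ratios, library_sizes=libs
    )


def background_ratio(
    ratios: pd.DataFrame, catalog: FeatureCatalog
) -> pd.Series:
    """Per-replicate background: median me2/H3 ratio over features that
    are not annotated heterochromatin blocks (genes and 'other')."""
    bg_ids = [
        f.feature_id
        for f in catalog.features
        if f.fclass not in HETEROCHROMATIN_CLASSES
    ]
    if not bg_ids:
        raise ValueError("no non-heterochromatin features; cannot estimate background")
    return ratios.reindex(bg_ids).median(axis=0, skipna=True)


def detect_enriched(
    ratios: pd.DataFrame,
    catalog: FeatureCatalog,
    enrichment_factor: float = 2.0,
    candidates: list[str] | None = None,
    min_replicates: int | None = None,
) -> list[str]:
    """Candidate features reproducibly enriched above background.

    The background is the per-replicate median ratio over
    non-heterochromatin features of the full table; a candidate is
    flagged when its ratio is >= ``enrichment_factor`` x background in
    at least ``min_replicates`` replicates (default: all of them, the
    strict reading of "reproducible"). ``candidates`` defaults to the
    annotated heterochromatin-class features present in the table — the
    analysis asks which *reported* domains show enrichment, not for
    de-novo domain discovery. Ratios at exactly background are not
    flagged for any factor > 1.
    """
    if ratios.shape[1] < 1:
        raise ValueError("need at least one replicate column")
    k = ratios.shape[1] if min_replicates is None else min_replicates
    bg = background_ratio(ratios, catalog)
    if candidates is None:
        het = {f.feature_id for f in catalog.heterochromatin}
        candidates = [i for i in ratios.index if i in het]
    cand = ratios.reindex(candidates)
    passing = (cand >= enrichment_factor * bg).sum(axis=1)
    return cand.index[passing >= k].tolist()


def compare_conditions(
    wt: pd.DataFrame,
    mutant: pd.DataFrame,
    reduction_factor: float = 2.0,
    wt_background: pd.Series | None = None,
    mutant_background: pd.Series | None = None,
    wt_h3: pd.DataFrame | None = None,
    mutant_h3: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature mutant/WT ratio fold and reduced/unchanged/increased call.

    ``fold`` is the ratio of replicate-mean ratios. The call is
    ``reduced`` when mutant/WT <= 1/``reduction_factor`` in *every*
    replicate pairing (each mutant replicate against each WT replicate),
    ``increased`` symmetrically, otherwise ``unchanged``. Features with
    an undefined ratio in either condition are reported as
    ``not_evaluable`` rather than silently dropped.

    When per-replicate backgrounds (from :func:`background_ratio`) are
    supplied, each condition's ratios are first divided by its own
    background. Per-million read normalization makes RPKM sensitive to
    library composition — a condition that loses methylation in its
    domains redistributes those reads genome-wide, inflating every other
    ratio — and background rescaling removes that bias, so the fold of
    an untouched feature is centred on 1.

    If H3 RPKM tables are given, their fold is reported in parallel
    (``h3_fold``) so a methylation call can be checked against histone
    occupancy.
    """
    if not wt.index.equals(mutant.index):
        mutant = mutant.reindex(wt.index)
    if wt_background is not None:
        wt = wt / wt_background
    if mutant_background is not None:
        mutant = mutant / mutant_background
    w = wt.to_numpy(float)
    m = mutant.to_numpy(float)

    def row_mean(x: np.ndarray) -> np.ndarray:
        finite = np.isfinite(x)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(finite, x, 0.0).sum(axis=1) / finite.sum(axis=1)
        return out

    mean_w = row_mean(w)
    mean_m = row_mean(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_m / mean_w
        # all pairwise mutant_j / wt_i folds per feature
        pair = m[:, np.newaxis, :] / w[:, :, np.newaxis]
    evaluable = np.all(np.isfinite(w), axis=1) & np.all(np.isfinite(m), axis=1)
    all_reduced = np.all(pair <= 1.0 / reduction_factor, axis=(1, 2))
    all_increased = np.all(pair >= reduction_factor, axis=(1, 2))
    call = np.where(
        ~evaluable,
        "not_evaluable",
        np.where(all_reduced, "reduced", np.where(all_increased, "increased", "unchanged")),
    )
    out = pd.DataFrame(
        {
            "wt_ratio": mean_w,
            "mutant_ratio": mean_m,
            "fold": fold,
            "call": call,
        },
        index=wt.index,
    )
    if wt_h3 is not None and mutant_h3 is not None:
        h3w = row_mean(wt_h3.reindex(wt.index).to_numpy(float))
        h3m = row_mean(mutant_h3.reindex(wt.index).to_numpy(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            out["h3_fold"] = h3m / h3w
    return out


def class_summary(
    table: OccupancyTable,
    catalog: FeatureCatalog,
    wt_condition: str,
    mutant_conditions: list[str] | None = None,
    reduction_factor: float = 2.0,
) -> pd.DataFrame:
    """One row per feature, grouped by feature class, with ratios, folds
    and calls per mutant condition; classes with no called changes show
    every row as ``unchanged``."""
    if wt_condition not in table.ratios:
        raise KeyError(f"no ratios for condition {wt_condition!r}")
    if mutant_conditions is None:
        mutant_conditions = [c for c in table.ratios if c != wt_condition]
    rows = pd.DataFrame(
        {
            "fclass": pd.Categorical(
                [f.fclass for f in catalog.features],
                categories=[
                    "island",
                    "subtelomere",
                    "centromere",
                    "transposon",
                    "HOOD",
                    "mRNA",
                    "ncRNA",
                    "other",
                ],
            ),
        },
        index=pd.Index(catalog.ids(), name="feature_id"),
    )
    wt_ratios = table.ratios[wt_condition]
    rows["wt_ratio"] = wt_ratios.mean(axis=1).reindex(rows.index)
    for cond in mutant_conditions:
        cmp = compare_conditions(
            wt_ratios,
            table.ratios[cond],
            reduction_factor=reduction_factor,
            wt_background=background_ratio(wt_ratios, catalog),
            mutant_background=background_ratio(table.ratios[cond], catalog),
            wt_h3=table.h3_rpkm(wt_condition),
            mutant_h3=table.h3_rpkm(cond),
        )
        rows[f"{cond}_fold"] = cmp["fold"].reindex(rows.index)
        rows[f"{cond}_call"] = cmp["call"].reindex(rows.index)
        if "h3_fold" in cmp:
            rows[f"{cond}_h3_fold"] = cmp["h3_fold"].reindex(rows.index)
    return rows.sort_values("fclass", kind="stable")


def write_bedgraph(
    readset_me2: ReadSet,
    readset_h3: ReadSet,
    chrom_sizes: dict[str, int],
    path: str | Path,
    bin_size: int = 500,
) -> Path:
    """Binned me2/H3 ratio track for browser-style inspection.

    Bins with zero H3 coverage are omitted (the ratio is undefined there).
    """
    path = Path(path)
    scale = readset_h3.n_reads / max(readset_me2.n_reads, 1)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{readset_me2.sample}_over_H3"\n')
        for chrom, length in chrom_sizes.items():
            edges = np.arange(0, length + bin_size, bin_size)
            me2 = np.histogram(readset_me2.starts.get(chrom, np.empty(0)), bins=edges)[0]
            h3 = np.histogram(readset_h3.starts.get(chrom, np.empty(0)), bins=edges)[0]
            for i in range(len(edges) - 1):
                if h3[i] > 0:
                    v = scale * me2[i] / h3[i]
                    fh.write(f"{chrom}\t{edges[i]}\t{min(edges[i+1], length)}\t{v:.4f}\n")
    return path
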