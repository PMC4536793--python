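"""Seeded generators for every input the pipeline consumes.

Each generator plants a known structure — a bound-target gene set, signed
expression fold-changes, methylated chromatin domains with
condition-specific loss, a qPCR abundance ratio — so that every analysis
stage can be asserted against ground truth. All randomness flows from a
single seed through labelled substreams, so any one generator is
reproducible independently of call order.

The default parameters are the study's conditions at desk scale: ~40-50
bound targets and ~80 differentially expressed genes among 5,000 array
features; 21 candidate heterochromatin islands of which 6 carry planted
methylation and 5 lose it in the mutant; subtelomeric blocks whose distal
nucleation sub-blocks never lose methylation; an 8-fold methylation
enrichment over background with the mutant retaining 20% of the excess;
50-bp reads.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pombechip.annotation_io import FeatureCatalog, GenomicFeature
from pombechip.matrix import EnrichmentMatrix
from pombechip.occupancy import ReadSet, SampleKey
from pombechip.qpcr import CtMeasurement


class ConfigError(ValueError):
    """Raised when a synthetic configuration is infeasible."""


@dataclass
class RipchipParams:
    n_targets: int = 50
    target_effect: float = 3.0  # log2 enrichment shift of bound targets
    noise_sd: float = 0.5  # log2 units
    n_replicates: int = 2


@dataclass
class ExpressionParams:
    n_de: int = 80  # scale of the mutant expression changes (~78-90 RNAs)
    de_log2fc: float = 1.5
    noise_sd: float = 0.3
    n_replicates: int = 3
    dye_bias_amplitude: float = 0.0  # smooth additive trend vs intensity


@dataclass
class ChipParams:
    genome_length: int = 1_500_000
    read_length: int = 50
    n_reads_per_channel: int = 100_000
    island_me2_enrichment: float = 8.0  # fold over background density
    mutant_loss_fraction: float = 0.2  # fraction of excess me2 retained when lost
    n_replicates: int = 2
    n_candidate_islands: int = 21
    n_methylated_islands: int = 6
    n_lost_islands: int = 5
    h3_domain_factor: float = 1.0  # <1 simulates nucleosome depletion in domains
    mutant_condition: str = "ccr4"


@dataclass
class QpcrParams:
    true_ratio: float = 8.0
    ct_noise_sd: float = 0.1  # cycles
    n_replicates: int = 3


@dataclass
class SynthConfig:
    seed: int = 0
    n_genes: int = 5000
    n_probes_per_gene: int = 1
    gene_length: int = 200
    gene_gap: int = 50
    ripchip: RipchipParams = field(default_factory=RipchipParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    chip: ChipParams = field(default_factory=ChipParams)
    qpcr: QpcrParams = field(default_factory=QpcrParams)

    def validate(self) -> None:
        if self.ripchip.n_targets > self.n_genes:
            raise ConfigError("n_targets exceeds n_genes")
        if self.expression.n_de > self.n_genes:
            raise ConfigError("n_de exceeds n_genes")
        if self.qpcr.true_ratio <= 0:
            raise ConfigError("qpcr true_ratio must be positive")
        if not 0 <= self.chip.mutant_loss_fraction <= 1:
            raise ConfigError("mutant_loss_fraction must lie in [0, 1]")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


@dataclass
class GroundTruth:
    """Planted structure the analysis stages are expected to recover."""

    target_ids: set[str]
    de_log2fc: dict[str, float]  # gene id -> signed planted log2 fold-change
    methylated_domains: dict[str, set[str]]  # condition -> fully methylated ids
    qpcr_true_ratio: float

    @property
    def de_ids(self) -> set[str]:
        return set(self.de_log2fc)

    def lost_domains(self, condition: str, wt: str = "wt") -> set[str]:
        """Domains methylated in ``wt`` but not fully retained in ``condition``."""
        return self.methylated_domains[wt] - self.methylated_domains[condition]

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "target_ids": sorted(self.target_ids),
            "de_log2fc": dict(sorted(self.de_log2fc.items())),
            "methylated_domains": {
                c: sorted(ids) for c, ids in self.methylated_domains.items()
            },
            "qpcr_true_ratio": self.qpcr_true_ratio,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label random substream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

_CHROM_FRACTIONS = {"chrI": 0.40, "chrII": 0.35, "chrIII": 0.25}
_SUBTEL_LEN = 20_000
_DISTAL_LEN = 5_000
_CEN_LEN = 15_000
_BLOCK_LEN = 4_000  # transposon / HOOD blocks
_ISLAND_GENES = 12  # genes spanned by one candidate island


def make_genome(config: SynthConfig) -> FeatureCatalog:
    """Deterministic toy genome with genes and chromatin blocks.

    Three chromosomes carry: four subtelomeric blocks (chrI/chrII ends),
    each split into a proximal block and a distal nucleation sub-block;
    one centromere (chrI, central); two transposon and two HOOD blocks
    (chrIII); candidate heterochromatin islands laid over runs of genes
    (islands overlap genes, as in the real annotation); and ``n_genes``
    genes tiled into the remaining territory.
    """
    config.validate()
    L = config.chip.genome_length
    sizes = {c: int(L * frac) for c, frac in _CHROM_FRACTIONS.items()}
    features: list[GenomicFeature] = []
    # reserved blocks (no genes inside): subtelomeres, centromere,
    # transposons, HOODs
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}

    def add_block(fid: str, chrom: str, start: int, end: int, fclass: str) -> None:
        features.append(GenomicFeature(fid, chrom, start, end, ".", fclass))
        reserved[chrom].append((start, end))

    for chrom, tag in (("chrI", "1"), ("chrII", "2")):
        Lc = sizes[chrom]
        if Lc < 3 * _SUBTEL_LEN:
            raise ConfigError(f"{chrom} too short for subtelomeric blocks")
        features.append(
            GenomicFeature(f"subtel_{tag}L_distal", chrom, 0, _DISTAL_LEN, ".", "subtelomere")
        )
        features.append(
            GenomicFeature(f"subtel_{tag}L", chrom, _DISTAL_LEN, _SUBTEL_LEN, ".", "subtelomere")
        )
        features.append(
            GenomicFeature(
                f"subtel_{tag}R", chrom, Lc - _SUBTEL_LEN, Lc - _DISTAL_LEN, ".", "subtelomere"
            )
        )
        features.append(
            GenomicFeature(f"subtel_{tag}R_distal", chrom, Lc - _DISTAL_LEN, Lc, ".", "subtelomere")
        )
        reserved[chrom] += [(0, _SUBTEL_LEN), (Lc - _SUBTEL_LEN, Lc)]
    mid = sizes["chrI"] // 2
    add_block("cen1", "chrI", mid - _CEN_LEN // 2, mid + _CEN_LEN // 2, "centromere")
    off = sizes["chrIII"] // 6
    add_block("tf2_1", "chrIII", off, off + _BLOCK_LEN, "transposon")
    add_block("tf2_2", "chrIII", 2 * off, 2 * off + _BLOCK_LEN, "transposon")
    add_block("hood_1", "chrIII", 3 * off, 3 * off + _BLOCK_LEN, "HOOD")
    add_block("hood_2", "chrIII", 4 * off, 4 * off + _BLOCK_LEN, "HOOD")

    # free territory per chromosome
    territory: list[tuple[str, int, int]] = []
    for chrom, Lc in sizes.items():
        blocks = sorted(reserved[chrom])
        pos = 0
        for bs, be in blocks:
            if bs > pos:
                territory.append((chrom, pos, bs))
            pos = max(pos, be)
        if pos < Lc:
            territory.append((chrom, pos, Lc))

    # tile genes into the territory
    pitch = config.gene_length + config.gene_gap
    rng = substream(config.seed, "genome")
    genes: list[GenomicFeature] = []
    width = len(str(max(config.n_genes, 1)))
    for chrom, ts, te in territory:
        pos = ts
        while pos + config.gene_length <= te and len(genes) < config.n_genes:
            gid = f"gene_{len(genes) + 1:0{width}d}"
            strand = "+" if rng.random() < 0.5 else "-"
            # a sprinkling of ncRNAs, mirroring the ncRNA island targets
            fclass = "ncRNA" if (len(genes) + 1) % 40 == 0 else "mRNA"
            genes.append(
                GenomicFeature(gid, chrom, pos, pos + config.gene_length, strand, fclass)
            )
            pos += pitch
        if len(genes) >= config.n_genes:
            break
    if len(genes) < config.n_genes:
        raise ConfigError(
            f"genome_length {L} too small to place {config.n_genes} genes "
            f"(placed {len(genes)})"
        )
    features.extend(genes)

    # candidate islands over evenly spaced runs of genes
    n_cand = config.chip.n_candidate_islands
    if n_cand > 0:
        if genes:
            if len(genes) < n_cand * (_ISLAND_GENES + 2):
                raise ConfigError(
                    f"not enough genes ({len(genes)}) for {n_cand} candidate islands"
                )
            stride = len(genes) // n_cand
            for j in range(n_cand):
                full = genes[j * stride : j * stride + _ISLAND_GENES]
                # keep only the leading positionally contiguous run, so an
                # island never straddles a reserved block or chromosome end
                run = [full[0]]
                for g in full[1:]:
                    if g.chrom == run[-1].chrom and g.start == run[-1].start + pitch:
                        run.append(g)
                    else:
                        break
                features.append(
                    GenomicFeature(
                        f"island_{j + 1:02d}", run[0].chrom, run[0].start, run[-1].end, ".", "island"
                    )
                )
        else:
            chrom, ts, te = territory[0]
            span = 3_000
            if te - ts < n_cand * 2 * span:
                raise ConfigError("territory too small for candidate islands")
            for j in range(n_cand):
                s = ts + j * 2 * span
                features.append(
                    GenomicFeature(f"island_{j + 1:02d}", chrom, s, s + span, ".", "island")
                )
    return FeatureCatalog(features=features, chrom_sizes=sizes)


def make_truth(config: SynthConfig, catalog: FeatureCatalog) -> GroundTruth:
    """Plant the ground truth over a generated genome.

    RIP-chip targets and DE genes are random gene subsets (the DE set
    deliberately overlaps the target set on a handful of genes, so the
    overlap statistics stage has signal to find). Methylated domains in
    the wild type are the first ``n_methylated_islands`` candidate
    islands plus all subtelomeric blocks, the centromere, transposons
    and HOODs; the mutant condition loses the first ``n_lost_islands``
    islands and all proximal subtelomeric blocks, while distal
    nucleation sub-blocks, the centromere, transposons and HOODs retain
    full methylation.
    """
    config.validate()
    gene_ids = [f.feature_id for f in catalog.genes]
    rng = substream(config.seed, "truth")
    targets = set(
        rng.choice(gene_ids, size=config.ripchip.n_targets, replace=False)
    ) if config.ripchip.n_targets else set()

    n_de = config.expression.n_de
    # overlap the DE set with targets on ~10% of it (at most the target count)
    n_shared = min(len(targets), max(1, n_de // 10)) if n_de and targets else 0
    shared = set(rng.choice(sorted(targets), size=n_shared, replace=False)) if n_shared else set()
    rest_pool = [g for g in gene_ids if g not in targets]
    rest = set(rng.choice(rest_pool, size=n_de - n_shared, replace=False)) if n_de else set()
    de_ids = sorted(shared | rest)
    signs = rng.choice([1.0, -1.0], size=len(de_ids))
    de_log2fc = {
        g: float(s * config.expression.de_log2fc) for g, s in zip(de_ids, signs)
    }

    cp = config.chip
    islands = [f.feature_id for f in catalog.by_class("island")]
    meth_islands = islands[: cp.n_methylated_islands]
    lost_islands = meth_islands[: cp.n_lost_islands]
    subtel = [f.feature_id for f in catalog.by_class("subtelomere")]
    distal = [s for s in subtel if s.endswith("_distal")]
    proximal = [s for s in subtel if not s.endswith("_distal")]
    always = (
        set(distal)
        | {f.feature_id for f in catalog.by_class("centromere", "transposon", "HOOD")}
    )
    wt_set = set(meth_islands) | set(proximal) | always
    mutant_set = (set(meth_islands) - set(lost_islands)) | always
    return GroundTruth(
        target_ids=set(targets),
        de_log2fc=de_log2fc,
        methylated_domains={"wt": wt_set, cp.mutant_condition: mutant_set},
        qpcr_true_ratio=config.qpcr.true_ratio,
    )


# ---------------------------------------------------------------------------
# microarray generators
# ---------------------------------------------------------------------------


def _array_matrix(
    gene_ids: list[str],
    shifts: pd.Series,
    noise_sd: float,
    n_replicates: int,
    n_probes: int,
    rng: np.random.Generator,
    prefix: str,
) -> pd.DataFrame:
    """Planted-shift + Gaussian-noise replicate matrix; probes per gene
    are independent draws averaged to the gene level."""
    n = len(gene_ids)
    base = shifts.reindex(gene_ids).fillna(0.0).to_numpy()[:, None]
    noise = rng.normal(0.0, noise_sd, size=(n, n_replicates, max(n_probes, 1)))
    vals = base + noise.mean(axis=2)
    return pd.DataFrame(
        vals, index=gene_ids, columns=[f"{prefix}_rep{i + 1}" for i in range(n_replicates)]
    )


def simulate_ripchip(config: SynthConfig, truth: GroundTruth, catalog: FeatureCatalog) -> EnrichmentMatrix:
    """log2(IP/total) enrichments: bound targets shifted by
    ``target_effect``, everything else pure noise."""
    gene_ids = [f.feature_id for f in catalog.genes]
    unknown = truth.target_ids - set(gene_ids)
    if unknown:
        raise ConfigError(f"planted targets not in catalog: {sorted(unknown)[:5]}")
    rp = config.ripchip
    shifts = pd.Series(
        {g: rp.target_effect for g in truth.target_ids}, dtype=float
    )
    rng = substream(config.seed, "ripchip")
    vals = _array_matrix(
        gene_ids, shifts, rp.noise_sd, rp.n_replicates, config.n_probes_per_gene, rng, "rip"
    )
    return EnrichmentMatrix(values=vals, channel="rip")


def simulate_expression(
    config: SynthConfig, truth: GroundTruth, catalog: FeatureCatalog
) -> tuple[EnrichmentMatrix, pd.DataFrame]:
    """Mutant-vs-WT log2 ratios plus a mean-intensity table.

    DE genes carry their signed planted fold-change; an optional smooth
    intensity-dependent dye bias (amplitude ``dye_bias_amplitude``) is
    added per array to exercise Loess normalization.
    """
    gene_ids = [f.feature_id for f in catalog.genes]
    ep = config.expression
    shifts = pd.Series(truth.de_log2fc, dtype=float)
    rng = substream(config.seed, "expression")
    vals = _array_matrix(
        gene_ids, shifts, ep.noise_sd, ep.n_replicates, config.n_probes_per_gene, rng, "expr"
    )
    # log2 mean spot intensities, uniform over the usual scanner range
    inten = pd.DataFrame(
        rng.uniform(6.0, 16.0, size=vals.shape), index=vals.index, columns=vals.columns
    )
    if ep.dye_bias_amplitude:
        bias = ep.dye_bias_amplitude * np.cos(np.pi * (inten.to_numpy() - 6.0) / 10.0)
        vals = vals + bias
    return EnrichmentMatrix(values=vals, channel="expression"), inten


# ---------------------------------------------------------------------------
# ChIP-seq read generator
# ---------------------------------------------------------------------------


def _domain_segments(
    catalog: FeatureCatalog,
    truth: GroundTruth,
    condition: str,
    enrichment: float,
    loss_fraction: float,
) -> list[tuple[str, int, int, float]]:
    """(chrom, start, end, excess_weight_per_bp) for every WT domain.

    Fully methylated domains carry excess (enrichment - 1); lost domains
    retain ``loss_fraction`` of that excess.
    """
    wt_set = truth.methylated_domains["wt"]
    cond_set = truth.methylated_domains.get(condition, wt_set)
    segs = []
    for f in catalog.features:
        if f.feature_id not in wt_set:
            continue
        excess = enrichment - 1.0
        if f.feature_id not in cond_set:
            excess *= loss_fraction
        if excess > 0:
            segs.append((f.chrom, f.start, f.end, excess))
    return segs


def _draw_reads(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    segments: list[tuple[str, int, int, float]],
    n_reads: int,
    read_length: int,
) -> dict[str, np.ndarray]:
    """Sample read starts from a uniform background plus weighted excess
    segments (mixture sampling: background mass = genome length, each
    segment adds excess x length)."""
    chroms = list(chrom_sizes)
    comp_w = [float(chrom_sizes[c]) for c in chroms]  # background per chrom
    comp = [("bg", c, 0, chrom_sizes[c]) for c in chroms]
    for chrom, s, e, excess in segments:
        comp.append(("seg", chrom, s, e))
        comp_w.append(excess * (e - s))
    w = np.asarray(comp_w)
    counts = rng.multinomial(n_reads, w / w.sum())
    starts: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    for (kind, chrom, s, e), k in zip(comp, counts):
        if k == 0:
            continue
        hi = max(e - read_length, s + 1)
        starts[chrom].append(rng.integers(s, hi, size=k))
    return {
        c: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64)
        for c, v in starts.items()
    }


def simulate_chip_reads(
    config: SynthConfig,
    truth: GroundTruth,
    catalog: FeatureCatalog,
    condition: str,
) -> list[ReadSet]:
    """Aligned-read sets for channels H3, H3K9me2 and input of one
    condition, across ``n_replicates`` replicates.

    H3 and input are uniform over the genome (optionally H3 is depleted
    within domains by ``h3_domain_factor``); H3K9me2 density is
    ``island_me2_enrichment``-fold higher inside the condition's
    methylated domains, with lost domains retaining
    ``mutant_loss_fraction`` of the excess.
    """
    cp = config.chip
    me2_segs = _domain_segments(
        catalog, truth, condition, cp.island_me2_enrichment, cp.mutant_loss_fraction
    )
    if cp.h3_domain_factor != 1.0:
        wt = truth.methylated_domains["wt"]
        h3_segs = [
            (f.chrom, f.start, f.end, cp.h3_domain_factor - 1.0)
            for f in catalog.features
            if f.feature_id in wt
        ]
    else:
        h3_segs = []
    readsets = []
    for rep in range(1, cp.n_replicates + 1):
        for antibody, segs in (("H3", h3_segs), ("H3K9me2", me2_segs), ("input", [])):
            rng = substream(config.seed, f"chip:{condition}:{antibody}:{rep}")
            starts = _draw_reads(
                rng, catalog.chrom_sizes, segs, cp.n_reads_per_channel, cp.read_length
            )
            readsets.append(
                ReadSet(
                    sample=SampleKey(antibody, condition, rep),
                    starts=starts,
                    read_length=cp.read_length,
                )
            )
    return readsets


# ---------------------------------------------------------------------------
# qPCR generator
# ---------------------------------------------------------------------------

_BASE_CT = {
    ("reference", "IP"): 24.0,
    ("reference", "INPUT"): 20.0,
    ("target", "INPUT"): 26.0,
}


def simulate_qpcr(config: SynthConfig) -> list[CtMeasurement]:
    """Ct quartets constructed so 2^-ddCt recovers ``true_ratio`` exactly
    at zero noise; Gaussian cycle noise (sd ``ct_noise_sd``) per well."""
    config.validate()
    qp = config.qpcr
    rng = substream(config.seed, "qpcr")
    target_ip = (
        _BASE_CT[("target", "INPUT")]
        + (_BASE_CT[("reference", "IP")] - _BASE_CT[("reference", "INPUT")])
        - np.log2(qp.true_ratio)
    )
    out = []
    for rep in range(1, qp.n_replicates + 1):
        for (gene, fraction), base in {**_BASE_CT, ("target", "IP"): target_ip}.items():
            ct = base + (rng.normal(0.0, qp.ct_noise_sd) if qp.ct_noise_sd > 0 else 0.0)
            out.append(CtMeasurement(gene=gene, fraction=fraction, ct=float(ct), replicate=rep))
    return out
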