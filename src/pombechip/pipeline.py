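"""Stage orchestration: file-level wiring of the analysis stages plus an
end-to-end synthetic demonstration run.

Every stage writes its outputs atomically (staged in a temporary
directory, then moved into place) together with a run manifest echoing
the configuration, the seed and the package version, so the thresholds
behind every call are auditable from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import pombechip
from pombechip import annotation_io, diffexpr, occupancy, overlap, qpcr, ripchip
from pombechip.matrix import EnrichmentMatrix
from pombechip.occupancy import SampleKey
from pombechip import synthetic

STAGES = ("simulate", "ripchip", "diffexpr", "overlap", "chip", "qpcr")


@dataclass
class PipelineConfig:
    """Paths and stage parameters; every default is echoed into the manifest."""

    outdir: str = "pombechip_out"
    seed: int = 0
    # input paths (stage-dependent; simulate fills them in)
    catalog: str | None = None
    chrom_sizes: str | None = None
    rip_matrix: str | None = None
    expr_matrix: str | None = None
    intensities: str | None = None
    reads_dir: str | None = None
    ct_table: str | None = None
    gene_lists: dict[str, str] = field(default_factory=dict)
    universe: str | None = None
    # stage parameters
    z_threshold: float = 2.5
    rule_k: int = 2
    fdr_threshold: float = 0.005
    n_permutations: int = 100
    s0_percentile: float = 5.0
    loess_span: float = 0.3
    enrichment_factor: float = 2.0
    reduction_factor: float = 2.0
    wt_condition: str = "wt"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    """A stage failed after configuration validation."""


class ConfigurationError(ValueError):
    """Invalid or incomplete configuration for the requested stage."""


def _require_paths(config: PipelineConfig, *names: str) -> None:
    for name in names:
        p = getattr(config, name)
        if p is None:
            raise ConfigurationError(f"stage requires config path {name!r}")
        if not Path(p).exists():
            raise ConfigurationError(f"input file for {name!r} not found: {p}")


def _write_manifest(stage: str, config: PipelineConfig, tmp: Path) -> None:
    manifest = {
        "stage": stage,
        "package_version": pombechip.__version__,
        "config": dataclasses.asdict(config),
    }
    (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _publish(tmp: Path, outdir: Path) -> list[Path]:
    """Move staged outputs into the output directory (atomic per file)."""
    outdir.mkdir(parents=True, exist_ok=True)
    moved = []
    for f in sorted(tmp.iterdir()):
        dest = outdir / f.name
        if dest.is_dir():
            shutil.rmtree(dest)
        shutil.move(str(f), str(dest))
        moved.append(dest)
    return moved


def run_stage(stage: str, config: PipelineConfig) -> list[Path]:
    """Run one pipeline stage; returns the published output paths.

    Raises :class:`ConfigurationError` for invalid configuration (CLI
    exit status 2) and :class:`StageError` for runtime failures (exit
    status 1). No partial outputs are left behind on failure.
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(config.outdir)
    runner = {
        "simulate": _stage_simulate,
        "ripchip": _stage_ripchip,
        "diffexpr": _stage_diffexpr,
        "overlap": _stage_overlap,
        "chip": _stage_chip,
        "qpcr": _stage_qpcr,
    }[stage]
    with tempfile.TemporaryDirectory(prefix=f"pombechip_{stage}_") as td:
        tmp = Path(td)
        _write_manifest(stage, config, tmp)
        try:
            runner(config, tmp)
        except (ConfigurationError, StageError):
            raise
        except Exception as exc:  # stage failure, not config failure
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        return _publish(tmp, outdir)


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, tmp: Path) -> None:
    sc = synthetic.SynthConfig(seed=config.seed)
    catalog = synthetic.make_genome(sc)
    truth = synthetic.make_truth(sc, catalog)
    annotation_io.write_features(catalog, tmp / "catalog.tsv", "TSV")
    annotation_io.write_features(catalog, tmp / "catalog.bed", "BED")
    annotation_io.write_chrom_sizes(catalog.chrom_sizes, tmp / "chrom_sizes.tsv")
    truth.to_json(tmp / "ground_truth.json")
    sc.to_json(tmp / "synth_config.json")

    simulate_matrix = synthetic.simulate_ripchip(sc, truth, catalog)
    simulate_matrix.to_tsv(tmp / "rip_matrix.tsv")
    expr, inten = synthetic.simulate_expression(sc, truth, catalog)
    expr.to_tsv(tmp / "expr_matrix.tsv")
    inten.to_csv(tmp / "intensities.tsv", sep="\t", index_label="gene_id")

    reads_dir = tmp / "reads"
    reads_dir.mkdir()
    for condition in truth.methylated_domains:
        for rs in synthetic.simulate_chip_reads(sc, truth, catalog, condition):
            rs.to_bed(reads_dir / f"reads_{rs.sample.antibody}_{rs.sample.condition}_{rs.sample.replicate}.bed")

    qpcr.write_ct_table(synthetic.simulate_qpcr(sc), tmp / "ct_table.tsv")


def _stage_ripchip(config: PipelineConfig, tmp: Path) -> None:
    _require_paths(config, "rip_matrix")
    matrix = EnrichmentMatrix.from_tsv(config.rip_matrix, channel="rip")
    centred = ripchip.mean_centre(matrix)
    z = ripchip.zscores(centred)
    calls = ripchip.call_targets(
        z, threshold=config.z_threshold, rule=(config.rule_k, z.shape[1])
    )
    z.to_csv(tmp / "zscores.tsv", sep="\t", index_label="gene_id")
    calls.to_tsv(tmp / "targets.tsv")


def _stage_diffexpr(config: PipelineConfig, tmp: Path) -> None:
    _require_paths(config, "expr_matrix")
    matrix = EnrichmentMatrix.from_tsv(config.expr_matrix, channel="expression")
    if config.intensities:
        _require_paths(config, "intensities")
        inten = pd.read_csv(config.intensities, sep="\t", index_col=0)
        matrix = diffexpr.loess_normalize(matrix, inten, span=config.loess_span)
    results = diffexpr.sam_fdr(
        matrix,
        n_permutations=config.n_permutations,
        seed=config.seed,
        fdr_threshold=config.fdr_threshold,
    )
    diffexpr.write_de_results(results, tmp / "de_results.tsv")
    up, down = diffexpr.called_sets(results)
    (tmp / "de_up.txt").write_text("".join(f"{g}\n" for g in sorted(up)))
    (tmp / "de_down.txt").write_text("".join(f"{g}\n" for g in sorted(down)))


def _stage_overlap(config: PipelineConfig, tmp: Path) -> None:
    if len(config.gene_lists) < 2:
        raise ConfigurationError("overlap stage needs >= 2 entries in gene_lists")
    if config.universe is None:
        raise ConfigurationError("overlap stage needs an explicit universe path")
    _require_paths(config, "universe")
    for name, p in config.gene_lists.items():
        if not Path(p).exists():
            raise ConfigurationError(f"gene list {name!r} not found: {p}")
    universe = overlap.read_gene_list(config.universe)
    sets = {name: overlap.read_gene_list(p) for name, p in config.gene_lists.items()}
    results = overlap.overlap_summary(sets, universe)
    overlap.write_overlap_table(results, tmp / "overlap.tsv")


def _stage_chip(config: PipelineConfig, tmp: Path) -> None:
    _require_paths(config, "catalog", "reads_dir")
    catalog = annotation_io.load_features(
        config.catalog,
        "TSV",
        chrom_sizes=annotation_io.load_chrom_sizes(config.chrom_sizes)
        if config.chrom_sizes
        else None,
    )
    reads_dir = Path(config.reads_dir)
    readsets = []
    for bed in sorted(reads_dir.glob("reads_*.bed")):
        _, antibody, condition, rep = bed.stem.split("_", 3)
        key = SampleKey(antibody, condition, int(rep))
        readsets.append(occupancy.read_bed_reads(bed, key))
    sams = sorted(reads_dir.glob("reads_*.sam"))
    for sam in sams:
        _, antibody, condition, rep = sam.stem.split("_", 3)
        readsets.append(occupancy.read_sam_reads(sam, SampleKey(antibody, condition, int(rep))))
    if not readsets:
        raise ConfigurationError(f"no reads_*.bed / reads_*.sam files in {reads_dir}")
    table = occupancy.quantify(readsets, catalog)
    table.rpkm.to_csv(tmp / "rpkm.tsv", sep="\t", index_label="feature_id")
    summary = occupancy.class_summary(
        table, catalog, config.wt_condition, reduction_factor=config.reduction_factor
    )
    with open(tmp / "class_summary.tsv", "w") as fh:
        fh.write(
            f"# enrichment_factor={config.enrichment_factor}\t"
            f"reduction_factor={config.reduction_factor}\n"
        )
        summary.to_csv(fh, sep="\t")
    het_ids = [f.feature_id for f in catalog.heterochromatin]
    enriched = occupancy.detect_enriched(
        table.ratios[config.wt_condition],
        catalog,
        enrichment_factor=config.enrichment_factor,
        candidates=het_ids,
    )
    (tmp / "enriched_features.txt").write_text("".join(f"{x}\n" for x in enriched))
    # one ratio track per condition for browser-style inspection
    by_key = {str(rs.sample): rs for rs in readsets}
    for cond in table.ratios:
        me2 = by_key.get(str(SampleKey("H3K9me2", cond, 1)))
        h3 = by_key.get(str(SampleKey("H3", cond, 1)))
        if me2 and h3:
            occupancy.write_bedgraph(me2, h3, catalog.chrom_sizes, tmp / f"me2_h3_{cond}.bedgraph")


def _stage_qpcr(config: PipelineConfig, tmp: Path) -> None:
    _require_paths(config, "ct_table")
    measurements = qpcr.read_ct_table(config.ct_table)
    summary = qpcr.ddct_summary(measurements)
    qpcr.write_summary(summary, tmp / "qpcr_summary.tsv")


# ---------------------------------------------------------------------------
# end-to-end demonstration on synthetic data
# ---------------------------------------------------------------------------


def run_demo(seed: int, outdir: str | Path | None = None) -> dict:
    """Generate a toy study and push it through every stage, reporting
    planted-truth recovery with pass/fail checks.

    Checks (all at the generator's default effect sizes):

    * RIP-chip: sensitivity and precision of the called target set vs
      the planted bound set, both >= 0.9.
    * Differential expression: power >= 0.9 and precision >= 0.9 at the
      configured FDR.
    * Overlap: the planted target/DE intersection is detected with
      Fisher p < 0.01.
    * ChIP occupancy: enriched candidates == planted methylated islands;
      reduced calls == planted lost domains; distal subtelomeric
      sub-blocks never called reduced.
    * qPCR: recovered ratio within 1.4-fold of the planted ratio.
    """
    sc = synthetic.SynthConfig(seed=seed)
    catalog = synthetic.make_genome(sc)
    truth = synthetic.make_truth(sc, catalog)
    report: dict = {"seed": seed, "checks": {}}

    def check(name: str, passed: bool, **detail) -> None:
        report["checks"][name] = {"pass": bool(passed), **detail}

    # RIP-chip
    rip = synthetic.simulate_ripchip(sc, truth, catalog)
    calls = ripchip.call_targets(ripchip.zscores(ripchip.mean_centre(rip)))
    called = set(calls.called_ids)
    tp = len(called & truth.target_ids)
    sens = tp / max(len(truth.target_ids), 1)
    prec = tp / max(len(called), 1)
    check("ripchip_recovery", sens >= 0.9 and prec >= 0.9, sensitivity=sens, precision=prec)

    # differential expression
    expr, inten = synthetic.simulate_expression(sc, truth, catalog)
    de = diffexpr.sam_fdr(expr, n_permutations=100, seed=seed)
    de_called = {r.gene_id for r in de if r.called}
    de_tp = len(de_called & truth.de_ids)
    power = de_tp / max(len(truth.de_ids), 1)
    de_prec = de_tp / max(len(de_called), 1)
    check("de_recovery", power >= 0.9 and de_prec >= 0.9, power=power, precision=de_prec)

    # overlap of called targets with called DE genes
    universe = {f.feature_id for f in catalog.genes}
    ov = overlap.fisher_overlap(called, de_called, universe, "rip_targets", "de_genes")
    planted_shared = len(truth.target_ids & truth.de_ids)
    check(
        "overlap_detected",
        ov.p_value < 0.01,
        observed=ov.observed,
        expected=ov.expected,
        p_value=ov.p_value,
        planted_shared=planted_shared,
    )

    # ChIP occupancy
    mutant = sc.chip.mutant_condition
    readsets = [
        rs
        for cond in ("wt", mutant)
        for rs in synthetic.simulate_chip_reads(sc, truth, catalog, cond)
    ]
    table = occupancy.quantify(readsets, catalog)
    het_ids = [f.feature_id for f in catalog.heterochromatin]
    enriched = set(
        occupancy.detect_enriched(table.ratios["wt"], catalog, candidates=het_ids)
    )
    planted_meth = truth.methylated_domains["wt"]
    cmp = occupancy.compare_conditions(
        table.ratios["wt"].loc[het_ids],
        table.ratios[mutant].loc[het_ids],
        wt_background=occupancy.background_ratio(table.ratios["wt"], catalog),
        mutant_background=occupancy.background_ratio(table.ratios[mutant], catalog),
    )
    reduced = set(cmp.index[cmp["call"] == "reduced"])
    planted_lost = truth.lost_domains(mutant)
    distal = {i for i in het_ids if i.endswith("_distal")}
    check(
        "chip_enrichment_recovery",
        enriched == planted_meth,
        n_enriched=len(enriched),
        n_planted=len(planted_meth),
        spurious=sorted(enriched - planted_meth),
        missed=sorted(planted_meth - enriched),
    )
    check(
        "chip_reduction_recovery",
        reduced == planted_lost and not (reduced & distal),
        n_reduced=len(reduced),
        n_planted_lost=len(planted_lost),
        distal_called=sorted(reduced & distal),
    )

    # qPCR
    summary = qpcr.ddct_summary(synthetic.simulate_qpcr(sc))
    log_err = abs(np.log2(summary.mean_ratio / truth.qpcr_true_ratio))
    check(
        "qpcr_recovery",
        log_err < 0.5,
        recovered_ratio=summary.mean_ratio,
        true_ratio=truth.qpcr_true_ratio,
    )

    report["all_pass"] = all(c["pass"] for c in report["checks"].values())
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "demo_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
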