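"""Genomic feature catalogs: the flat-interval annotation every ChIP-seq
quantification step runs over.

Internal coordinates are 0-based half-open (BED convention). GFF input
(1-based closed) is converted at the boundary, so downstream arithmetic
never sees mixed conventions. Features may overlap — heterochromatin
islands overlap the meiotic genes they silence — and no de-overlapping is
performed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

FEATURE_CLASSES = (
    "mRNA",
    "ncRNA",
    "island",
    "subtelomere",
    "centromere",
    "transposon",
    "HOOD",
    "other",
)

#: feature classes treated as heterochromatin blocks (excluded from the
#: background estimate in occupancy analysis)
HETEROCHROMATIN_CLASSES = frozenset(
    {"island", "subtelomere", "centromere", "transposon", "HOOD"}
)

_VALID_STRANDS = {"+", "-", "."}


class AnnotationParseError(ValueError):
    """Raised when a BED/GFF/TSV line cannot be parsed; names the line."""


@dataclass(frozen=True)
class GenomicFeature:
    """A labelled genomic interval with a feature class.

    Coordinates are 0-based half-open; ``strand`` is one of ``+ - .``.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    fclass: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")
        if self.fclass not in FEATURE_CLASSES:
            raise ValueError(f"feature {self.feature_id!r}: unknown class {self.fclass!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicFeature") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class FeatureCatalog:
    """Ordered collection of features plus chromosome sizes.

    Class-restricted views preserve input order; the union of per-class
    views partitions the catalog.
    """

    features: list[GenomicFeature] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self.features)

    def ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def by_id(self, feature_id: str) -> GenomicFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def by_class(self, *fclasses: str) -> list[GenomicFeature]:
        """Input-order view of features whose class is in ``fclasses``."""
        bad = set(fclasses) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        return [f for f in self.features if f.fclass in fclasses]

    @property
    def heterochromatin(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.fclass in HETEROCHROMATIN_CLASSES]

    @property
    def genes(self) -> list[GenomicFeature]:
        return self.by_class("mRNA", "ncRNA")


def validate_catalog(catalog: FeatureCatalog) -> list[str]:
    """Check catalog invariants; return human-readable violations.

    An empty list means the catalog is valid. Violations name the
    offending feature_id; nothing is raised.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for f in catalog.features:
        if f.feature_id in seen:
            violations.append(f"duplicate feature_id {f.feature_id!r}")
        seen.add(f.feature_id)
        if f.chrom not in catalog.chrom_sizes:
            violations.append(
                f"feature {f.feature_id!r}: chromosome {f.chrom!r} not in chrom_sizes"
            )
        elif f.end > catalog.chrom_sizes[f.chrom]:
            violations.append(
                f"feature {f.feature_id!r}: end {f.end} exceeds {f.chrom} "
                f"length {catalog.chrom_sizes[f.chrom]}"
            )
    return violations


def _parse_bed_line(fields: list[str], lineno: int) -> GenomicFeature:
    if len(fields) < 4:
        raise AnnotationParseError(f"line {lineno}: BED record needs >= 4 columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-integer coordinates") from exc
    strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else "."
    try:
        return GenomicFeature(fields[3], fields[0], start, end, strand)
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


def _parse_gff_line(fields: list[str], lineno: int) -> GenomicFeature:
    if len(fields) < 9:
        raise AnnotationParseError(f"line {lineno}: GFF3 record needs 9 columns")
    try:
        start1, end1 = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-integer coordinates") from exc
    attrs = dict(
        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
    )
    fid = attrs.get("ID") or attrs.get("Name")
    if fid is None:
        raise AnnotationParseError(f"line {lineno}: GFF attributes lack ID/Name")
    fclass = fields[2] if fields[2] in FEATURE_CLASSES else "other"
    strand = fields[6] if fields[6] in _VALID_STRANDS else "."
    try:
        # GFF is 1-based closed: decrement start on load
        return GenomicFeature(fid, fields[0], start1 - 1, end1, strand, fclass)
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


def _parse_tsv_line(fields: list[str], lineno: int) -> GenomicFeature:
    # feature_id, chrom, start, end, strand, fclass (0-based half-open)
    if len(fields) < 6:
        raise AnnotationParseError(f"line {lineno}: TSV record needs 6 columns")
    try:
        return GenomicFeature(
            fields[0], fields[1], int(fields[2]), int(fields[3]), fields[4], fields[5]
        )
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


_PARSERS = {"BED": _parse_bed_line, "GFF": _parse_gff_line, "TSV": _parse_tsv_line}
_TSV_HEADER = ["feature_id", "chrom", "start", "end", "strand", "fclass"]


def load_features(
    path: str | Path,
    format: str = "BED",
    chrom_sizes: dict[str, int] | None = None,
) -> FeatureCatalog:
    """Load a feature catalog from BED6, GFF3 or the internal TSV dialect.

    Coordinates are converted to 0-based half-open on load. ``chrom_sizes``
    may be supplied to enable bounds validation; absent, they default to
    the per-chromosome max feature end.
    """
    fmt = format.upper()
    if fmt not in _PARSERS:
        raise ValueError(f"unknown format {format!r}; expected BED, GFF or TSV")
    parse = _PARSERS[fmt]
    features: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "TSV" and lineno == 1 and fields[:2] == _TSV_HEADER[:2]:
                continue  # header row
            features.append(parse(fields, lineno))
    if chrom_sizes is None:
        chrom_sizes = {}
        for f in features:
            chrom_sizes[f.chrom] = max(chrom_sizes.get(f.chrom, 0), f.end)
    return FeatureCatalog(features=features, chrom_sizes=dict(chrom_sizes))


def write_features(
    catalog: FeatureCatalog, path: str | Path, format: str = "BED"
) -> Path:
    """Write a catalog as BED6, GFF3 or TSV; round-trips coordinate-exactly."""
    fmt = format.upper()
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "BED":
            for f in catalog.features:
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n"
                )
        elif fmt == "GFF":
            fh.write("##gff-version 3\n")
            for f in catalog.features:
                fh.write(
                    f"{f.chrom}\tpombechip\t{f.fclass}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID={f.feature_id}\n"
                )
        elif fmt == "TSV":
            fh.write("\t".join(_TSV_HEADER) + "\n")
            for f in catalog.features:
                fh.write(
                    f"{f.feature_id}\t{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t{f.fclass}\n"
                )
        else:
            raise ValueError(f"unknown format {format!r}")
    return path


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, length) -> dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise AnnotationParseError(f"line {lineno}: need chrom and length")
            sizes[row[0]] = int(row[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    return path
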