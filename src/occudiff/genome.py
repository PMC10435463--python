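"""Genomic coordinate frame, gene annotation and feature classification.

All coordinates are 0-based, half-open (BED convention). GTF input, which is
1-based closed, is converted on read. A genomic point is classified into one
of four mutually exclusive categories — promoter, exon, intron, intergenic —
under a fixed priority rule (promoter wins over exonic/intronic overlap), so
category fractions over any interval set sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree


class GenomeFormatError(ValueError):
    """Malformed input file (parse-level problem)."""


class GenomeValidationError(ValueError):
    """Well-formed input violating a semantic invariant."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; the coordinate frame for all intervals."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GenomeValidationError(f"duplicate chromosome names: {dup}")
        for name, length in self.chromosomes:
            if length <= 0:
                raise GenomeValidationError(
                    f"chromosome {name!r} has non-positive length {length}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise GenomeValidationError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise GenomeValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, exon blocks, and a strand-derived TSS."""

    gene_id: str
    interval: Interval
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise GenomeValidationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.interval.strand!r}"
            )
        if not self.exons:
            raise GenomeValidationError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise GenomeValidationError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise GenomeValidationError(
                    f"gene {self.gene_id}: exon [{ex.start},{ex.end}) outside gene interval"
                )
            if prev_end is not None and ex.start < prev_end:
                raise GenomeValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Transcription start site: interval start on +, interval end on -."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class GeneSet:
    """Gene models keyed by id, tied to a genome layout."""

    genes: dict[str, GeneModel]
    layout: GenomeLayout

    def __post_init__(self) -> None:
        for gid, g in self.genes.items():
            if g.interval.chrom not in self.layout:
                raise GenomeValidationError(f"gene {gid}: unknown chromosome {g.interval.chrom}")
            if g.interval.end > self.layout.length_of(g.interval.chrom):
                raise GenomeValidationError(
                    f"gene {gid}: interval extends past end of {g.interval.chrom}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())


class FeatureCategory(str, Enum):
    PROMOTER = "promoter"
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class AnnotationConfig:
    """Promoter window half-widths around the TSS, in bp.

    The window is strand-oriented: [tss - upstream, tss + downstream) for a
    + strand gene and the mirror image for a - strand gene.
    """

    promoter_upstream: int = 2000
    promoter_downstream: int = 2000

    def __post_init__(self) -> None:
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise GenomeValidationError("promoter extents must be >= 0")
        if self.promoter_upstream == 0 and self.promoter_downstream == 0:
            raise GenomeValidationError("promoter window cannot be empty")


# ---------------------------------------------------------------------------
# readers


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column chrom.sizes TSV into a GenomeLayout (file order kept)."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenomeFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            name, length_s = parts
            try:
                length = int(length_s)
            except ValueError as exc:
                raise GenomeFormatError(f"{path}:{lineno}: bad length {length_s!r}") from exc
            if length <= 0:
                raise GenomeValidationError(f"{path}:{lineno}: non-positive length {length}")
            chroms.append((name, length))
    if not chroms:
        raise GenomeFormatError(f"{path}: no chromosomes")
    return GenomeLayout(tuple(chroms))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def _parse_bed12_line(parts: list[str], lineno: int, path) -> GeneModel:
    chrom, start_s, end_s, name, _score, strand = parts[:6]
    start, end = int(start_s), int(end_s)
    if strand not in {"+", "-"}:
        raise GenomeValidationError(f"{path}:{lineno}: gene {name}: missing/invalid strand")
    if len(parts) >= 12:
        n_blocks = int(parts[9])
        sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise GenomeFormatError(f"{path}:{lineno}: blockCount disagrees with block lists")
        exons = tuple(
            Interval(chrom, start + off, start + off + sz, strand)
            for off, sz in zip(offsets, sizes)
        )
    else:
        exons = (Interval(chrom, start, end, strand),)
    return GeneModel(name, Interval(chrom, start, end, strand), exons)


def read_gene_annotation(path: str | Path, layout: GenomeLayout) -> GeneSet:
    """Read gene models from BED12 (preferred), BED6, or minimal GTF.

    Format is sniffed from the extension: ``.gtf``/``.gff`` parse as GTF
    (gene/exon records, 1-based closed converted to 0-based half-open),
    anything else as BED.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        genes = _read_gtf(path)
    else:
        genes = _read_bed(path)
    return GeneSet(genes, layout)


def _read_bed(path: Path) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise GenomeFormatError(f"{path}:{lineno}: need >= 6 BED fields")
            gene = _parse_bed12_line(parts, lineno, path)
            if gene.gene_id in genes:
                raise GenomeValidationError(f"{path}:{lineno}: duplicate gene {gene.gene_id}")
            genes[gene.gene_id] = gene
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None


def _read_gtf(path: Path) -> dict[str, GeneModel]:
    spans: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise GenomeFormatError(f"{path}:{lineno}: need 9 GTF fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = parts[:9]
            if strand not in {"+", "-"}:
                raise GenomeValidationError(f"{path}:{lineno}: missing strand")
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise GenomeFormatError(f"{path}:{lineno}: no gene_id attribute")
            start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            if feature == "gene":
                spans[gid] = (chrom, start, end, strand)
            elif feature == "exon":
                exons.setdefault(gid, []).append(Interval(chrom, start, end, strand))
    genes: dict[str, GeneModel] = {}
    for gid, (chrom, start, end, strand) in spans.items():
        ex = tuple(sorted(exons.get(gid, [Interval(chrom, start, end, strand)]),
                          key=lambda iv: iv.start))
        genes[gid] = GeneModel(gid, Interval(chrom, start, end, strand), ex)
    # exon-only GTFs: synthesize the gene span from its exons
    for gid, ex_list in exons.items():
        if gid not in genes:
            ex = tuple(sorted(ex_list, key=lambda iv: iv.start))
            genes[gid] = GeneModel(
                gid,
                Interval(ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand),
                ex,
            )
    if not genes:
        raise GenomeFormatError(f"{path}: no gene records")
    return genes


def write_gene_annotation_bed12(geneset: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(geneset, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            sizes = ",".join(str(len(e)) for e in g.exons) + ","
            offs = ",".join(str(e.start - iv.start) for e in g.exons) + ","
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


# ---------------------------------------------------------------------------
# promoters & classification


def promoter_interval(gene: GeneModel, cfg: AnnotationConfig, layout: GenomeLayout) -> Interval:
    """Strand-oriented promoter window around the TSS, clipped to the chromosome."""
    up, down = cfg.promoter_upstream, cfg.promoter_downstream
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    chrom_len = layout.length_of(gene.interval.chrom)
    start, end = max(0, start), min(chrom_len, end)
    return Interval(gene.interval.chrom, start, end, gene.strand)


def promoters(geneset: GeneSet, cfg: AnnotationConfig) -> list[tuple[str, Interval]]:
    """Per-gene promoter windows (gene_id, interval), clipped to bounds."""
    return [
        (g.gene_id, promoter_interval(g, cfg, geneset.layout))
        for g in geneset
    ]


class FeatureIndex:
    """Interval-tree index over promoters, exons and gene bodies for fast lookup.

    Rebuilding the trees per query would dominate bin/peak classification, so
    classify_point/classify_interval accept (and the pipeline reuses) one of
    these.
    """

    def __init__(self, geneset: GeneSet, cfg: AnnotationConfig | None = None) -> None:
        cfg = cfg or AnnotationConfig()
        self.geneset = geneset
        self.cfg = cfg
        self._promoters: dict[str, IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        for g in geneset:
            chrom = g.interval.chrom
            piv = promoter_interval(g, cfg, geneset.layout)
            self._promoters.setdefault(chrom, IntervalTree()).addi(piv.start, piv.end)
            self._bodies.setdefault(chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end
            )
            for ex in g.exons:
                self._exons.setdefault(chrom, IntervalTree()).addi(ex.start, ex.end)

    def classify(self, chrom: str, pos: int) -> FeatureCategory:
        if chrom not in self.geneset.layout:
            raise GenomeValidationError(f"unknown chromosome {chrom!r}")
        if self._promoters.get(chrom, IntervalTree()).overlaps(pos):
            return FeatureCategory.PROMOTER
        if self._exons.get(chrom, IntervalTree()).overlaps(pos):
            return FeatureCategory.EXON
        if self._bodies.get(chrom, IntervalTree()).overlaps(pos):
            return FeatureCategory.INTRON
        return FeatureCategory.INTERGENIC


def classify_point(
    chrom: str,
    pos: int,
    geneset: GeneSet,
    cfg: AnnotationConfig | None = None,
    index: FeatureIndex | None = None,
) -> FeatureCategory:
    """Classify a genomic point with priority promoter > exon > intron > intergenic."""
    if index is None:
        index = FeatureIndex(geneset, cfg)
    return index.classify(chrom, pos)


def classify_interval(
    iv: Interval,
    geneset: GeneSet,
    cfg: AnnotationConfig | None = None,
    index: FeatureIndex | None = None,
) -> FeatureCategory:
    """Classify an interval by its midpoint, keeping categories exclusive."""
    return classify_point(iv.chrom, iv.midpoint, geneset, cfg, index)
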