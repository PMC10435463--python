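"""Peak annotation and canonical-motif analysis.

Consumes already-called peak intervals (BED) with their sequences (FASTA):
assigns peaks to the nearest TSS, summarizes their genomic distribution, and
scans/tests enrichment of a consensus motif (default the AP-1/TRE site
TGACTCA bound by ATF3) against a composition-preserving shuffle null.
Peak calling itself is upstream and out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    AnnotationConfig,
    FeatureCategory,
    FeatureIndex,
    GeneSet,
    GenomeLayout,
    GenomeValidationError,
    Interval,
    classify_interval,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A consensus motif matched exactly; reverse-complement matches count as -."""

    consensus: str = "TGACTCA"
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise GenomeValidationError(
                f"motif consensus must be non-empty over ACGT, got {self.consensus!r}"
            )


@dataclass(frozen=True)
class Peak:
    peak_id: str
    interval: Interval
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != len(self.interval):
            raise GenomeValidationError(
                f"peak {self.peak_id}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self.interval)}"
            )


@dataclass
class PeakSet:
    peaks: list[Peak]
    layout: GenomeLayout

    def __post_init__(self) -> None:
        for p in self.peaks:
            if p.interval.chrom not in self.layout:
                raise GenomeValidationError(
                    f"peak {p.peak_id}: unknown chromosome {p.interval.chrom}"
                )
            if p.interval.end > self.layout.length_of(p.interval.chrom):
                raise GenomeValidationError(f"peak {p.peak_id}: interval out of bounds")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def sequences(self) -> list[str]:
        missing = [p.peak_id for p in self.peaks if p.sequence is None]
        if missing:
            raise GenomeValidationError(f"peaks without sequence: {missing[:5]} ...")
        return [p.sequence for p in self.peaks]  # type: ignore[misc]


def read_peaks_bed(path: str | Path, layout: GenomeLayout) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            pid = parts[3] if len(parts) > 3 else f"peak_{lineno}"
            peaks.append(Peak(pid, Interval(chrom, s, e)))
    return PeakSet(peaks, layout)


def write_peaks_bed(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peakset:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t0\t.\n")


def read_peak_sequences(peakset: PeakSet, fasta_path: str | Path) -> PeakSet:
    """Attach sequences keyed by peak_id from a FASTA file."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    peaks = []
    for p in peakset:
        if p.peak_id not in seqs:
            raise GenomeValidationError(f"no FASTA record for peak {p.peak_id}")
        peaks.append(Peak(p.peak_id, p.interval, seqs[p.peak_id]))
    return PeakSet(peaks, peakset.layout)


def write_peak_sequences(peakset: PeakSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.peak_id, description="")
        for p in peakset
        if p.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# peak → gene assignment and genomic distribution


def assign_peaks_to_genes(
    peakset: PeakSet,
    geneset: GeneSet,
    max_distance: int = 100_000,
) -> dict[str, str | None]:
    """Assign each peak to the gene with the nearest TSS (by peak midpoint).

    Peaks farther than ``max_distance`` from every TSS are unassigned (None).
    Equidistant TSSs break ties toward the lexicographically smaller gene_id.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in geneset:
        by_chrom.setdefault(g.interval.chrom, []).append((g.tss, g.gene_id))
    for lst in by_chrom.values():
        lst.sort()
    out: dict[str, str | None] = {}
    for p in peakset:
        cands = by_chrom.get(p.interval.chrom)
        if not cands:
            out[p.peak_id] = None
            continue
        mid = p.interval.midpoint
        tss_arr = [t for t, _ in cands]
        i = int(np.searchsorted(tss_arr, mid))
        best: tuple[int, str] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(cands):
                d = abs(cands[j][0] - mid)
                if best is None or d < best[0] or (d == best[0] and cands[j][1] < best[1]):
                    best = (d, cands[j][1])
        # neighbours can share a TSS coordinate; sweep ties for the smallest id
        assert best is not None
        for t, gid in cands:
            if abs(t - mid) == best[0] and gid < best[1]:
                best = (best[0], gid)
        out[p.peak_id] = best[1] if best[0] <= max_distance else None
    return out


def peak_genomic_distribution(
    peakset: PeakSet,
    geneset: GeneSet,
    cfg: AnnotationConfig | None = None,
) -> dict[str, float]:
    """Fraction of peaks per genomic category (midpoint rule).

    Categories are promoter / intron / intergenic / other, where "other" is
    the exonic residual left implicit in three-category reports.
    """
    if len(peakset) == 0:
        raise GenomeValidationError("empty peak set")
    index = FeatureIndex(geneset, cfg)
    counts = {c: 0 for c in FeatureCategory}
    for p in peakset:
        counts[classify_interval(p.interval, geneset, cfg, index)] += 1
    n = len(peakset)
    return {
        "promoter": counts[FeatureCategory.PROMOTER] / n,
        "intron": counts[FeatureCategory.INTRON] / n,
        "intergenic": counts[FeatureCategory.INTERGENIC] / n,
        "other": counts[FeatureCategory.EXON] / n,
    }


# ---------------------------------------------------------------------------
# motif scanning and enrichment


def scan_motif(sequence: str, spec: MotifSpec = MotifSpec()) -> list[tuple[int, str]]:
    """All exact motif occurrences in a sequence, overlapping matches included.

    Returns (0-based offset, strand) pairs, '+' for the consensus itself and
    '-' for its reverse complement (skipped if the motif is its own reverse
    complement, or if both_strands is off). N never matches.
    """
    seq = sequence.upper()
    hits: list[tuple[int, str]] = []
    targets = [(spec.consensus, "+")]
    rc = reverse_complement(spec.consensus)
    if spec.both_strands and rc != spec.consensus:
        targets.append((rc, "-"))
    for pattern, strand in targets:
        start = seq.find(pattern)
        while start != -1:
            hits.append((start, strand))
            start = seq.find(pattern, start + 1)
    hits.sort()
    return hits


def _has_hit(seq_bytes: bytes, patterns: list[bytes]) -> bool:
    return any(p in seq_bytes for p in patterns)


def motif_enrichment(
    sequences: list[str],
    spec: MotifSpec = MotifSpec(),
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Empirical motif enrichment against a per-sequence shuffle null.

    The statistic is the number of sequences containing at least one match
    (either strand). Each null round shuffles every sequence independently,
    preserving its mononucleotide composition. Returns
    ``(n_with_hit, expected_under_null, p_empirical)`` with
    ``p = (1 + #{rounds with null statistic >= observed}) / (1 + n_shuffles)``.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    patterns = [spec.consensus.encode()]
    rc = reverse_complement(spec.consensus)
    if spec.both_strands and rc != spec.consensus:
        patterns.append(rc.encode())
    arrays = [np.frombuffer(s.upper().encode(), dtype=np.uint8).copy() for s in sequences]
    observed = sum(_has_hit(a.tobytes(), patterns) for a in arrays)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles, dtype=np.int64)
    for r in range(n_shuffles):
        count = 0
        for a in arrays:
            count += _has_hit(rng.permutation(a).tobytes(), patterns)
        null[r] = count
    expected = float(null.mean())
    p = float((1 + int((null >= observed).sum())) / (1 + n_shuffles))
    return observed, expected, p
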