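"""Synthetic genomes, coverage, expression and peaks with known planted truth.

The generator emulates the statistical structure the differential pipeline
assumes: depth-normalised count-like replicate coverage elevated over gene
bodies and promoters, a planted subset of genes whose occupancy is reduced
by a multiplicative factor in the KO condition, FPKM tables with planted
up/down-regulated genes, and fixed-width peak sequences with a planted
consensus motif in a known subset. Truth sets are assigned by exact counts
(round(fraction x n)) so recovery metrics have fixed denominators, and every
random draw derives from the config seed, with distinct sub-streams per
(condition, replicate).

Coverage noise: per-step values are negative-binomial counts drawn at
``depth_scale`` times the target mean and divided by ``depth_scale`` — the
shape CPM-scaled coverage takes. With the defaults (mean 10, depth_scale 5,
dispersion 50) the coefficient of variation is
sqrt(1/(10*5) + 1/50) = 0.20.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .expression import ExpressionTable, write_expression_tsv
from .genome import (
    AnnotationConfig,
    GeneModel,
    GeneSet,
    GenomeLayout,
    Interval,
    promoter_interval,
    write_chrom_sizes,
    write_gene_annotation_bed12,
)
from .peaks import Peak, PeakSet, reverse_complement, write_peaks_bed, write_peak_sequences
from .tracks import SignalTrack, write_bedgraph

CTRL = "Ctrl"
KO = "KO"


@dataclass(frozen=True)
class SimulationConfig:
    n_chroms: int = 3
    chrom_length: int = 4_000_000
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (2000, 8000)
    step: int = 50
    n_replicates: int = 3
    base_occupancy_mean: float = 10.0
    dispersion: float = 50.0      # negative-binomial size parameter
    depth_scale: float = 5.0      # raw counts drawn at this multiple of the mean
    background_divisor: float = 5.0
    frac_down_genes: float = 0.2
    occupancy_effect: float = 0.5  # multiplicative KO factor over affected regions
    frac_up_degs: float = 0.2
    frac_down_degs: float = 0.05
    deg_log2fc_mean: float = 3.0
    expression_noise_sd: float = 0.25  # log2-scale replicate noise
    baseline_log2_fpkm_mean: float = 4.0
    baseline_log2_fpkm_sd: float = 1.0
    n_peaks: int = 200
    peak_width: int = 200
    frac_promoter_peaks: float = 0.4
    motif: str = "TGACTCA"
    frac_motif_peaks: float = 0.8
    promoter_upstream: int = 2000
    promoter_downstream: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_down_genes", "frac_up_degs", "frac_down_degs",
                     "frac_motif_peaks", "frac_promoter_peaks"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up_degs + self.frac_down_degs > 1:
            raise ValueError("frac_up_degs + frac_down_degs must be <= 1")
        if not 0 < self.occupancy_effect <= 1:
            raise ValueError("occupancy_effect must be in (0, 1]")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("bad gene_length_range")

    @property
    def annotation(self) -> AnnotationConfig:
        return AnnotationConfig(self.promoter_upstream, self.promoter_downstream)


@dataclass
class SyntheticTruth:
    geneset: GeneSet
    down_occupancy_genes: set[str]
    up_deg_genes: set[str]
    down_deg_genes: set[str]
    motif_peaks: set[str]
    config: SimulationConfig

    def __post_init__(self) -> None:
        universe = set(self.geneset.genes)
        for name in ("down_occupancy_genes", "up_deg_genes", "down_deg_genes"):
            extra = getattr(self, name) - universe
            if extra:
                raise ValueError(f"{name} not in gene universe: {sorted(extra)[:5]}")
        if self.up_deg_genes & self.down_deg_genes:
            raise ValueError("a gene cannot be both an up- and a down-regulated DEG")


def _rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, *key)))


def simulate_genome(cfg: SimulationConfig) -> SyntheticTruth:
    """Place non-overlapping genes and draw all planted truth labels.

    Genes are spaced at least a promoter window apart so affected regions
    never overlap a neighbour. Truth sets use exact counts: the down-occupancy
    set is an independent draw from the DEG labels, so occupancy-down and
    up-DEG genes co-occur at the product rate, as the integration layer expects.
    """
    rng = _rng(cfg, 1)
    layout = GenomeLayout(tuple(
        (f"chr{i + 1}", cfg.chrom_length) for i in range(cfg.n_chroms)
    ))
    spacing = cfg.promoter_upstream + cfg.promoter_downstream
    lo, hi = cfg.gene_length_range

    # spread genes over chromosomes as evenly as possible
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    genes: dict[str, GeneModel] = {}
    gene_idx = 0
    for ci, (chrom, length) in enumerate(layout.chromosomes):
        n_c = per_chrom[ci]
        if n_c == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n_c)
        needed = int(lengths.sum()) + (n_c + 1) * spacing
        if needed > length:
            raise ValueError(
                f"cannot place {n_c} genes of up to {hi} bp on a {length} bp "
                f"chromosome with {spacing} bp spacing; enlarge the genome"
            )
        slack = length - needed
        # split the slack into n_c+1 gaps via sorted uniform cuts
        cuts = np.sort(rng.integers(0, slack + 1, size=n_c))
        gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
        pos = spacing + int(gaps[0])
        for gi in range(n_c):
            glen = int(lengths[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{gene_idx:05d}"
            interval = Interval(chrom, pos, pos + glen, strand)
            genes[gid] = GeneModel(gid, interval, _make_exons(interval, rng))
            gene_idx += 1
            pos += glen + spacing + int(gaps[gi + 1])
    geneset = GeneSet(genes, layout)

    ids = sorted(genes)
    n_down_occ = round(cfg.frac_down_genes * cfg.n_genes)
    occ_perm = rng.permutation(ids)
    down_occ = set(occ_perm[:n_down_occ].tolist())

    n_up = round(cfg.frac_up_degs * cfg.n_genes)
    n_dn = round(cfg.frac_down_degs * cfg.n_genes)
    deg_perm = rng.permutation(ids)
    up_degs = set(deg_perm[:n_up].tolist())
    down_degs = set(deg_perm[n_up:n_up + n_dn].tolist())

    n_motif = round(cfg.frac_motif_peaks * cfg.n_peaks)
    peak_ids = [f"peak_{i:05d}" for i in range(cfg.n_peaks)]
    motif_peaks = set(rng.permutation(peak_ids)[:n_motif].tolist())

    return SyntheticTruth(geneset, down_occ, up_degs, down_degs, motif_peaks, cfg)


def _make_exons(interval: Interval, rng: np.random.Generator) -> tuple[Interval, ...]:
    """1-3 exon blocks; the first starts at the gene start, the last ends at its end."""
    n_ex = int(rng.integers(1, 4))
    if n_ex == 1 or len(interval) < 6 * n_ex:
        return (interval,)
    cuts = np.sort(rng.choice(np.arange(1, len(interval)), size=2 * (n_ex - 1),
                              replace=False))
    bounds = [0, *cuts.tolist(), len(interval)]
    exons = []
    for i in range(n_ex):
        s, e = bounds[2 * i], bounds[2 * i + 1]
        exons.append(Interval(interval.chrom, interval.start + s,
                              interval.start + e, interval.strand))
    return tuple(exons)


def _affected_span(gene: GeneModel, cfg: SimulationConfig,
                   layout: GenomeLayout) -> tuple[int, int]:
    """Promoter ∪ gene body as a single span (they are adjacent by construction)."""
    prom = promoter_interval(gene, cfg.annotation, layout)
    return min(prom.start, gene.interval.start), max(prom.end, gene.interval.end)


def _nb_draw(rng: np.random.Generator, means: np.ndarray,
             cfg: SimulationConfig) -> np.ndarray:
    size = cfg.dispersion
    scaled = means * cfg.depth_scale
    p = size / (size + scaled)
    return rng.negative_binomial(size, p) / cfg.depth_scale


def simulate_tracks(
    truth: SyntheticTruth,
) -> dict[str, list[SignalTrack]]:
    """Per-condition replicate coverage tracks with planted occupancy loss.

    The per-step mean is base_occupancy_mean over each gene's promoter ∪
    gene body and base/background_divisor elsewhere; in the KO condition the
    mean over affected genes' spans is multiplied by occupancy_effect.
    Replicate r of each condition draws from sub-seed (seed, condition, r).
    """
    cfg = truth.config
    layout = truth.geneset.layout
    step = cfg.step

    mean_arrays: dict[str, dict[str, np.ndarray]] = {CTRL: {}, KO: {}}
    for chrom, length in layout.chromosomes:
        n = -(-length // step)
        base = np.full(n, cfg.base_occupancy_mean / cfg.background_divisor)
        mean_arrays[CTRL][chrom] = base
        mean_arrays[KO][chrom] = base.copy()
    for g in truth.geneset:
        chrom = g.interval.chrom
        s, e = _affected_span(g, cfg, layout)
        i0, i1 = s // step, -(-e // step)
        mean_arrays[CTRL][chrom][i0:i1] = cfg.base_occupancy_mean
        ko_mean = cfg.base_occupancy_mean
        if g.gene_id in truth.down_occupancy_genes:
            ko_mean *= cfg.occupancy_effect
        mean_arrays[KO][chrom][i0:i1] = ko_mean

    out: dict[str, list[SignalTrack]] = {}
    for cond_idx, cond in enumerate((CTRL, KO)):
        tracks = []
        for r in range(cfg.n_replicates):
            rng = _rng(cfg, 2, cond_idx, r)
            data = {
                chrom: _nb_draw(rng, means, cfg)
                for chrom, means in mean_arrays[cond].items()
            }
            tracks.append(SignalTrack(layout, step, data))
        out[cond] = tracks
    return out


def simulate_expression(
    truth: SyntheticTruth,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Ctrl and KO FPKM tables with planted DEGs.

    Baseline log2 FPKM per gene is normal; planted DEGs shift the KO mean by
    ±deg_log2fc_mean; each replicate adds log2-normal noise of sd
    expression_noise_sd.
    """
    cfg = truth.config
    rng = _rng(cfg, 3)
    ids = sorted(truth.geneset.genes)
    base_log2 = rng.normal(cfg.baseline_log2_fpkm_mean, cfg.baseline_log2_fpkm_sd,
                           size=len(ids))
    shift = np.zeros(len(ids))
    for i, gid in enumerate(ids):
        if gid in truth.up_deg_genes:
            shift[i] = cfg.deg_log2fc_mean
        elif gid in truth.down_deg_genes:
            shift[i] = -cfg.deg_log2fc_mean
    n_rep = cfg.n_replicates
    ctrl_vals = 2.0 ** (
        base_log2[:, None] + rng.normal(0, cfg.expression_noise_sd, (len(ids), n_rep))
    )
    ko_vals = 2.0 ** (
        (base_log2 + shift)[:, None]
        + rng.normal(0, cfg.expression_noise_sd, (len(ids), n_rep))
    )
    ctrl = ExpressionTable(ids, [f"Ctrl_{r + 1}" for r in range(n_rep)], ctrl_vals)
    ko = ExpressionTable(ids, [f"KO_{r + 1}" for r in range(n_rep)], ko_vals)
    return ctrl, ko


def simulate_peaks(truth: SyntheticTruth) -> PeakSet:
    """Fixed-width peaks near promoters and in intergenic space, with sequences.

    Sequences are uniform ACGT; each peak in the planted motif subset gets
    one exact motif instance (forward or reverse complement at random) at a
    random offset.
    """
    cfg = truth.config
    rng = _rng(cfg, 4)
    layout = truth.geneset.layout
    genes = [truth.geneset.genes[g] for g in sorted(truth.geneset.genes)]
    width = cfg.peak_width
    n_prom = round(cfg.frac_promoter_peaks * cfg.n_peaks)

    peaks: list[Peak] = []
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(cfg.n_peaks):
        pid = f"peak_{i:05d}"
        if i < n_prom and genes:
            g = genes[int(rng.integers(len(genes)))]
            center = g.tss + int(rng.integers(-500, 501))
            chrom = g.interval.chrom
        else:
            chrom, length = layout.chromosomes[int(rng.integers(len(layout.chromosomes)))]
            center = int(rng.integers(width, length - width))
        chrom_len = layout.length_of(chrom)
        start = min(max(0, center - width // 2), chrom_len - width)
        seq_arr = alphabet[rng.integers(0, 4, size=width)]
        seq = seq_arr.tobytes().decode()
        if pid in truth.motif_peaks:
            motif = cfg.motif if rng.random() < 0.5 else reverse_complement(cfg.motif)
            off = int(rng.integers(0, width - len(motif) + 1))
            seq = seq[:off] + motif + seq[off + len(motif):]
        peaks.append(Peak(pid, Interval(chrom, start, start + width), seq))
    return PeakSet(peaks, layout)


def write_fixtures(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input in its standard on-disk format plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    write_chrom_sizes(truth.geneset.layout, paths["chrom_sizes"])

    paths["genes"] = outdir / "genes.bed"
    write_gene_annotation_bed12(truth.geneset, paths["genes"])

    tracks = simulate_tracks(truth)
    for cond in (CTRL, KO):
        for r, track in enumerate(tracks[cond]):
            key = f"{cond.lower()}_rep{r + 1}"
            paths[key] = outdir / f"{key}.bedgraph"
            write_bedgraph(track, paths[key])

    ctrl_expr, ko_expr = simulate_expression(truth)
    paths["expr_ctrl"] = outdir / "expression_ctrl.tsv"
    paths["expr_ko"] = outdir / "expression_ko.tsv"
    write_expression_tsv(ctrl_expr, paths["expr_ctrl"])
    write_expression_tsv(ko_expr, paths["expr_ko"])

    peakset = simulate_peaks(truth)
    paths["peaks_bed"] = outdir / "peaks.bed"
    paths["peaks_fasta"] = outdir / "peaks.fasta"
    write_peaks_bed(peakset, paths["peaks_bed"])
    write_peak_sequences(peakset, paths["peaks_fasta"])

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "down_occupancy_genes": sorted(truth.down_occupancy_genes),
                "up_deg_genes": sorted(truth.up_deg_genes),
                "down_deg_genes": sorted(truth.down_deg_genes),
                "motif_peaks": sorted(truth.motif_peaks),
                "config": asdict(truth.config),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
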