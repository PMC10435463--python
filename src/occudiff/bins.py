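"""Genome-wide bin-level differential occupancy.

The genome is tiled into fixed bins (default 10 kb, last bin of each
chromosome may be shorter). Within each replicate pair (Ctrl rep i vs KO
rep i) a bin is dropped when the average of the two bin means falls below a
signal floor (default 1), and otherwise classified by the KO/Ctrl ratio
against a fold-change threshold (default 1.5, boundary inclusive). A bin is
reported as changed only when at least k of n replicate pairs agree on the
direction (default 2 of 3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

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
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"
CALL_FILTERED = "filtered"
CONSENSUS_NONE = "none"


@dataclass
class BinGrid:
    """Bins tiling each chromosome exactly, in layout order."""

    layout: GenomeLayout
    bin_size: int
    bins: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise GenomeValidationError("bin_size must be positive")
        if not self.bins:
            for name, length in self.layout.chromosomes:
                for s in range(0, length, self.bin_size):
                    self.bins.append(Interval(name, s, min(s + self.bin_size, length)))

    def __len__(self) -> int:
        return len(self.bins)


def tile_genome(layout: GenomeLayout, bin_size: int = 10_000) -> BinGrid:
    """Tile every chromosome into consecutive bins; the final bin may be short."""
    return BinGrid(layout, bin_size)


def bin_means(track: SignalTrack, grid: BinGrid) -> np.ndarray:
    """Length-weighted mean signal per bin."""
    if track.layout != grid.layout:
        raise GenomeValidationError("track and grid use different layouts")
    out = np.empty(len(grid))
    for i, b in enumerate(grid.bins):
        out[i] = track.window_mean(b.chrom, b.start, b.end)
    return out


@dataclass(frozen=True)
class BinClassConfig:
    min_mean_signal: float = 1.0
    fold_change: float = 1.5
    consensus_k: int = 2
    n_replicates: int = 3
    # filter on the Ctrl/KO pair average (default) or on each sample separately
    filter_per_sample: bool = False

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise GenomeValidationError("fold_change must be > 1")
        if not (1 <= self.consensus_k <= self.n_replicates):
            raise GenomeValidationError("need 1 <= consensus_k <= n_replicates")


def classify_bin_pair(ctrl_mean: float, ko_mean: float,
                      cfg: BinClassConfig = BinClassConfig()) -> str:
    """Classify one bin for one Ctrl/KO replicate pair.

    Filtered when the pair's average signal is below the floor; otherwise up
    when KO/Ctrl >= fold_change, down when <= 1/fold_change, else unchanged.
    A zero Ctrl mean that survives the filter is treated as an infinite
    ratio (up) with a warning.
    """
    if ctrl_mean < 0 or ko_mean < 0:
        raise GenomeValidationError("bin means must be >= 0")
    if cfg.filter_per_sample:
        low = min(ctrl_mean, ko_mean) < cfg.min_mean_signal
    else:
        low = (ctrl_mean + ko_mean) / 2 < cfg.min_mean_signal
    if low:
        return CALL_FILTERED
    if ctrl_mean == 0:
        warnings.warn("bin with zero Ctrl mean passed the signal filter; calling up")
        return CALL_UP
    ratio = ko_mean / ctrl_mean
    if ratio >= cfg.fold_change:
        return CALL_UP
    if ratio <= 1 / cfg.fold_change:
        return CALL_DOWN
    return CALL_UNCHANGED


def consensus_calls(per_replicate_calls: np.ndarray,
                    cfg: BinClassConfig = BinClassConfig()) -> np.ndarray:
    """k-of-n same-direction consensus per bin.

    per_replicate_calls: (n_bins, n_replicates) array of call strings.
    Consensus is a direction reached by >= k replicates; unchanged when >= k
    replicates call unchanged and no direction reaches k; otherwise none
    (conflicts, filtered-dominated bins, and two-direction ties included).
    """
    calls = np.asarray(per_replicate_calls, dtype=object)
    if calls.ndim != 2:
        raise GenomeValidationError("per_replicate_calls must be 2-D (bins x replicates)")
    k = cfg.consensus_k
    n_up = (calls == CALL_UP).sum(axis=1)
    n_down = (calls == CALL_DOWN).sum(axis=1)
    n_unch = (calls == CALL_UNCHANGED).sum(axis=1)
    out = np.full(len(calls), CONSENSUS_NONE, dtype=object)
    out[(n_unch >= k) & (n_up < k) & (n_down < k)] = CALL_UNCHANGED
    out[(n_up >= k) & (n_down < k)] = CALL_UP
    out[(n_down >= k) & (n_up < k)] = CALL_DOWN
    return out


@dataclass
class BinDiffTable:
    grid: BinGrid
    per_replicate_calls: np.ndarray  # (n_bins, n_replicates) of call strings
    consensus: np.ndarray            # (n_bins,) of up/down/unchanged/none
    ko_over_ctrl_ratio: np.ndarray   # (n_bins, n_replicates), NaN where undefined

    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.consensus, return_counts=True)
        out = {c: 0 for c in (CALL_UP, CALL_DOWN, CALL_UNCHANGED, CONSENSUS_NONE)}
        out.update(dict(zip(vals.tolist(), cnt.tolist())))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "chrom": [b.chrom for b in self.grid.bins],
            "start": [b.start for b in self.grid.bins],
            "end": [b.end for b in self.grid.bins],
        }
        n_rep = self.per_replicate_calls.shape[1]
        for r in range(n_rep):
            rows[f"ratio_rep{r + 1}"] = self.ko_over_ctrl_ratio[:, r]
            rows[f"call_rep{r + 1}"] = self.per_replicate_calls[:, r]
        rows["consensus"] = self.consensus
        return pd.DataFrame(rows)


def diff_bins(
    ctrl_tracks: list[SignalTrack],
    ko_tracks: list[SignalTrack],
    bin_size: int = 10_000,
    cfg: BinClassConfig = BinClassConfig(),
) -> BinDiffTable:
    """Full bin pipeline: tile, per-replicate classification, consensus."""
    if len(ctrl_tracks) != len(ko_tracks):
        raise GenomeValidationError("need equal numbers of Ctrl and KO tracks")
    if len(ctrl_tracks) != cfg.n_replicates:
        cfg = BinClassConfig(cfg.min_mean_signal, cfg.fold_change,
                             min(cfg.consensus_k, len(ctrl_tracks)),
                             len(ctrl_tracks), cfg.filter_per_sample)
    grid = tile_genome(ctrl_tracks[0].layout, bin_size)
    n_rep = len(ctrl_tracks)
    calls = np.empty((len(grid), n_rep), dtype=object)
    ratios = np.full((len(grid), n_rep), np.nan)
    for r in range(n_rep):
        cm = bin_means(ctrl_tracks[r], grid)
        km = bin_means(ko_tracks[r], grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(len(grid)):
                calls[i, r] = classify_bin_pair(cm[i], km[i], cfg)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[:, r] = np.where(cm > 0, km / np.where(cm > 0, cm, 1.0), np.nan)
    consensus = consensus_calls(calls, cfg)
    logger.info("bin diff: %s", dict(zip(*np.unique(consensus, return_counts=True))))
    return BinDiffTable(grid, calls, consensus, ratios)


def changed_bin_distribution(
    table: BinDiffTable,
    geneset: GeneSet,
    cfg_annot: AnnotationConfig | None = None,
) -> dict[str, dict[str, float]]:
    """Genomic-category fractions of consensus-changed bins, per direction.

    Bins are classified by midpoint; exonic and intronic midpoints are both
    reported under "gene_body", matching the three-way
    promoter / gene body / intergenic reporting convention. Fractions within
    each direction sum to 1; directions with no bins yield empty dicts.
    """
    index = FeatureIndex(geneset, cfg_annot)
    out: dict[str, dict[str, float]] = {}
    for direction in (CALL_UP, CALL_DOWN):
        idx = np.flatnonzero(table.consensus == direction)
        if len(idx) == 0:
            out[direction] = {}
            continue
        counts = {"promoter": 0, "gene_body": 0, "intergenic": 0}
        for i in idx:
            cat = classify_interval(table.grid.bins[i], geneset, index=index)
            if cat is FeatureCategory.PROMOTER:
                counts["promoter"] += 1
            elif cat is FeatureCategory.INTERGENIC:
                counts["intergenic"] += 1
            else:  # exon or intron: inside the gene body
                counts["gene_body"] += 1
        n = len(idx)
        out[direction] = {k: v / n for k, v in counts.items()}
    return out
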