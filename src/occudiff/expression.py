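"""Differential expression calling from FPKM tables.

The rule is a pure fold-change threshold on per-condition mean FPKM: a gene
is up if log2((mean_ko + c)/(mean_ctrl + c)) exceeds the threshold (default
2, i.e. 4-fold), down if it falls below the negative threshold, and
low_expression if neither condition mean reaches the expression floor. No
dispersion modelling or multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionTable:
    """Gene × sample FPKM matrix."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), FPKM >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if (self.values < 0).any():
            raise ValueError("negative FPKM values")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")

    def gene_means(self) -> pd.Series:
        """Arithmetic mean FPKM per gene across samples."""
        return pd.Series(self.values.mean(axis=1), index=self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def read_expression_tsv(path: str | Path) -> ExpressionTable:
    """Read a TSV with gene ids in the first column and samples in the rest."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    table.to_frame().rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class DEGConfig:
    log2fc_threshold: float = 2.0
    pseudocount: float = 0.1   # FPKM added to both means; guards zeros
    min_expression: float = 1.0  # floor on max(mean_ctrl, mean_ko)

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    mean_ctrl: float
    mean_ko: float
    log2fc: float
    call: str  # up | down | unchanged | low_expression


def compute_log2fc(mean_ctrl: float, mean_ko: float, pseudocount: float = 0.1) -> float:
    """log2((mean_ko + c) / (mean_ctrl + c)); antisymmetric in its arguments."""
    if mean_ctrl < 0 or mean_ko < 0:
        raise ValueError("means must be >= 0")
    if mean_ctrl + pseudocount == 0 or mean_ko + pseudocount == 0:
        raise ValueError("log2 fold change undefined: zero mean with zero pseudocount")
    return math.log2((mean_ko + pseudocount) / (mean_ctrl + pseudocount))


def call_degs(
    table_ctrl: ExpressionTable,
    table_ko: ExpressionTable,
    cfg: DEGConfig = DEGConfig(),
) -> list[DEGRecord]:
    """Call each gene up / down / unchanged / low_expression (strict thresholds).

    The low-expression floor is checked first; up/down require
    |log2fc| strictly above the threshold.
    """
    if set(table_ctrl.genes) != set(table_ko.genes):
        offenders = sorted(set(table_ctrl.genes) ^ set(table_ko.genes))
        raise ValueError(f"gene universes differ; offenders: {offenders[:10]}")
    mean_ctrl = table_ctrl.gene_means()
    mean_ko = table_ko.gene_means()
    records = []
    for gid in table_ctrl.genes:
        mc, mk = float(mean_ctrl[gid]), float(mean_ko[gid])
        lfc = compute_log2fc(mc, mk, cfg.pseudocount)
        if max(mc, mk) < cfg.min_expression:
            call = "low_expression"
        elif lfc > cfg.log2fc_threshold:
            call = "up"
        elif lfc < -cfg.log2fc_threshold:
            call = "down"
        else:
            call = "unchanged"
        records.append(DEGRecord(gid, mc, mk, lfc, call))
    return records


def deg_sets(records: list[DEGRecord]) -> tuple[set[str], set[str]]:
    """(up, down) gene-id sets."""
    up = {r.gene_id for r in records if r.call == "up"}
    down = {r.gene_id for r in records if r.call == "down"}
    return up, down


def summarize_degs(records: list[DEGRecord]) -> tuple[int, int, float | None, float | None]:
    """Counts of up/down DEGs and their percentages of all DEGs.

    Percentages are over up+down only, rounded to one decimal as reported;
    None when there are no DEGs at all.
    """
    n_up = sum(r.call == "up" for r in records)
    n_down = sum(r.call == "down" for r in records)
    total = n_up + n_down
    if total == 0:
        return 0, 0, None, None
    return (
        n_up,
        n_down,
        round(100.0 * n_up / total, 1),
        round(100.0 * n_down / total, 1),
    )


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "mean_ctrl": [r.mean_ctrl for r in records],
            "mean_ko": [r.mean_ko for r in records],
            "log2fc": [r.log2fc for r in records],
            "call": [r.call for r in records],
        }
    )
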