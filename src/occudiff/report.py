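"""Integration of DEG, bin, region and peak results into one report.

The headline products are gene-set intersections: genes whose peaks overlap
down-regulated DEGs, and genes losing occupancy at their promoter or gene
body that are simultaneously up-regulated — the link from local histone loss
to transcriptional activation. The report is deterministic: identical inputs
and seed give byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .bins import BinDiffTable, changed_bin_distribution
from .expression import DEGRecord, deg_sets, degs_to_frame, summarize_degs
from .genome import AnnotationConfig, GeneSet
from .regions import RegionDiffRecord

SCHEMA_VERSION = "1"


def intersect_gene_sets(a: set[str], b: set[str]) -> tuple[list[str], int]:
    """Sorted intersection and its size."""
    members = sorted(a & b)
    return members, len(members)


def down_h2b_gene_set(region_records: list[RegionDiffRecord]) -> set[str]:
    """Genes with consensus occupancy loss at promoter OR gene body."""
    return {r.gene_id for r in region_records if r.consensus == "down"}


def up_h2b_gene_set(region_records: list[RegionDiffRecord]) -> set[str]:
    return {r.gene_id for r in region_records if r.consensus == "up"}


@dataclass
class IntegrationReport:
    payload: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


class StageMissingError(ValueError):
    """A required pipeline stage output was not supplied."""


def build_report(
    deg_records: list[DEGRecord] | None,
    bin_table: BinDiffTable | None,
    region_records: list[RegionDiffRecord] | None,
    peak_gene_map: dict[str, str | None] | None,
    peak_distribution: dict[str, float] | None,
    motif_result: tuple[int, float, float] | None,
    geneset: GeneSet,
    config_snapshot: dict[str, Any],
    seed: int,
    annot_cfg: AnnotationConfig | None = None,
    outdir: str | Path | None = None,
) -> IntegrationReport:
    """Assemble (and optionally write) the cross-stage report.

    All stages must use the annotation's gene universe; unknown ids are a
    hard error. Writing is atomic (temp file + rename), so a crashed run
    never leaves a half-written report.
    """
    for stage, value in (
        ("expression_diff", deg_records),
        ("occupancy_bins", bin_table),
        ("region_diff", region_records),
    ):
        if value is None:
            raise StageMissingError(f"missing stage output: {stage}")
    assert deg_records is not None and bin_table is not None
    assert region_records is not None

    universe = set(geneset.genes)
    bad = {r.gene_id for r in deg_records} - universe
    bad |= {r.gene_id for r in region_records} - universe
    if peak_gene_map:
        bad |= {g for g in peak_gene_map.values() if g is not None} - universe
    if bad:
        raise ValueError(f"gene ids outside the annotation universe: {sorted(bad)[:10]}")

    n_up, n_down, frac_up, frac_down = summarize_degs(deg_records)
    up_degs, down_degs = deg_sets(deg_records)
    down_h2b = down_h2b_gene_set(region_records)
    up_h2b = up_h2b_gene_set(region_records)

    peak_targets = (
        {g for g in peak_gene_map.values() if g is not None} if peak_gene_map else set()
    )
    peaks_x_down_degs = intersect_gene_sets(peak_targets, down_degs)
    down_h2b_x_up_degs = intersect_gene_sets(down_h2b, up_degs)

    payload: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": config_snapshot,
        "deg_summary": {
            "n_up": n_up,
            "n_down": n_down,
            "pct_up": frac_up,
            "pct_down": frac_down,
        },
        "bin_summary": {
            "counts": bin_table.counts(),
            "n_bins": len(bin_table.grid),
            "changed_distribution": changed_bin_distribution(
                bin_table, geneset, annot_cfg
            ),
        },
        "region_summary": {
            "down_genes": sorted(down_h2b),
            "up_genes": sorted(up_h2b),
            "n_records": len(region_records),
        },
        "peak_summary": {
            "n_target_genes": len(peak_targets),
            "target_genes": sorted(peak_targets),
            "distribution": peak_distribution,
            "motif": (
                None
                if motif_result is None
                else {
                    "n_peaks_with_hit": motif_result[0],
                    "expected_under_null": motif_result[1],
                    "p_empirical": motif_result[2],
                }
            ),
        },
        "overlaps": {
            "peak_targets_x_down_degs": {
                "members": peaks_x_down_degs[0],
                "count": peaks_x_down_degs[1],
            },
            "down_h2b_x_up_degs": {
                "members": down_h2b_x_up_degs[0],
                "count": down_h2b_x_up_degs[1],
            },
        },
    }
    report = IntegrationReport(payload)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _atomic_write(outdir / "report.json", report.to_json())
        degs_to_frame(deg_records).to_csv(outdir / "degs.tsv", sep="\t", index=False)
        bin_table.to_frame().to_csv(outdir / "bins.tsv", sep="\t", index=False)
        _region_records_tsv(region_records, outdir / "regions.tsv")
    return report


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _region_records_tsv(records: list[RegionDiffRecord], path: Path) -> None:
    with open(path, "w") as fh:
        n_rep = max((len(r.replicates) for r in records), default=0)
        cols = ["gene_id", "region_kind"]
        for r in range(n_rep):
            cols += [f"U_rep{r + 1}", f"p_rep{r + 1}", f"ratio_rep{r + 1}", f"call_rep{r + 1}"]
        cols.append("consensus")
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            row = [rec.gene_id, rec.region_kind]
            for rep in rec.replicates:
                row += [f"{rep.u:g}", f"{rep.p:.6g}", f"{rep.ratio:.6g}", rep.call]
            row.append(rec.consensus)
            fh.write("\t".join(row) + "\n")
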