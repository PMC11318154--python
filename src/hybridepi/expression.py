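"""Expression quantification (RPKM), binning and differential-expression calls.

RPKM is reads per kilobase of exonic gene length per million mapped reads.
Expression bins follow the four-class scheme: non (RPKM = 0),
low (0 < RPKM <= 1), medium (1 < RPKM <= 8), high (RPKM > 8).

Differential expression between two cultivars uses the same pooled two-sided
Fisher's exact engine as the histone-modification calls, with
Benjamini-Hochberg FDR across all tested genes; a gene is differential at
FDR < 0.05 and |log2FC| >= 1, *up* meaning higher in the first contrast
member.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .io import CountTable
from .stats import bh_adjust, fisher_count_test
from .types import CONTRASTS, DEGRecord, GeneModel

log = logging.getLogger(__name__)

DEG_LOG2FC_MIN = 1.0
DEG_FDR_MAX = 0.05

EXPRESSION_BINS = ("non", "low", "medium", "high")


def compute_rpkm(count: int, gene_length_bp: int, library_size: int) -> float:
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (gene_length_bp / 1000) / (library_size / 1e6)


def assign_expression_bin(rpkm: float) -> str:
    if rpkm < 0:
        raise ValueError("RPKM cannot be negative")
    if rpkm == 0:
        return "non"
    if rpkm <= 1:
        return "low"
    if rpkm <= 8:
        return "medium"
    return "high"


def rpkm_table(counts: CountTable, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Replicate-pooled RPKM per gene x cultivar, with bins.

    Gene length is the exonic length (standard RPKM semantics).
    """
    lengths = {g.gene_id: g.exonic_length for g in genes}
    cultivars = sorted({c.split("_")[0] for c in counts.counts.columns})
    rows = []
    for cultivar in cultivars:
        pooled, lib = counts.pooled(cultivar)
        for gid, n in pooled.items():
            if gid not in lengths:
                log.debug("gene %s absent from gene models; skipped", gid)
                continue
            rpkm = compute_rpkm(int(n), lengths[gid], lib)
            rows.append(
                {
                    "gene_id": gid, "cultivar": cultivar, "count": int(n),
                    "rpkm": rpkm, "bin": assign_expression_bin(rpkm),
                }
            )
    return pd.DataFrame(rows)


def call_degs(
    counts: CountTable,
    contrast: str,
    log2fc_min: float = DEG_LOG2FC_MIN,
    fdr_max: float = DEG_FDR_MAX,
) -> list[DEGRecord]:
    """Differential-expression calls for one contrast over all shared genes."""
    a, b = CONTRASTS[contrast]
    pooled_a, lib_a = counts.pooled(a)
    pooled_b, lib_b = counts.pooled(b)
    gene_ids = sorted(counts.counts.index)
    results = []
    for gid in gene_ids:
        log2fc, pvalue = fisher_count_test(int(pooled_a[gid]), lib_a, int(pooled_b[gid]), lib_b)
        results.append((gid, log2fc, pvalue))
    fdrs = bh_adjust([p for _, _, p in results])
    records = []
    for (gid, log2fc, pvalue), fdr in zip(results, fdrs):
        if fdr < fdr_max and log2fc >= log2fc_min:
            status = "up"
        elif fdr < fdr_max and log2fc <= -log2fc_min:
            status = "down"
        else:
            status = "ns"
        records.append(DEGRecord(gid, contrast, log2fc, pvalue, float(fdr), status))
    return records


def expression_by_target_status(
    rpkms: pd.DataFrame, target_sets: Mapping[str, set[str]]
) -> pd.DataFrame:
    """RPKM distribution of target vs non-target genes per mark and cultivar."""
    rows = []
    universe = set(rpkms["gene_id"])
    for mark, targets in sorted(target_sets.items()):
        if not targets <= universe:
            raise ValueError(f"{mark} target set extends beyond the expression universe")
        for cultivar, sub in rpkms.groupby("cultivar"):
            for group, mask in (
                ("target", sub["gene_id"].isin(targets)),
                ("non-target", ~sub["gene_id"].isin(targets)),
            ):
                vals = sub.loc[mask, "rpkm"]
                rows.append(
                    {
                        "mark": mark, "cultivar": cultivar, "group": group,
                        "n": int(len(vals)),
                        "median_rpkm": float(vals.median()) if len(vals) else float("nan"),
                        "mean_rpkm": float(vals.mean()) if len(vals) else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def modification_by_expression_bin(
    signal_per_gene: Mapping[str, float], rpkms: pd.DataFrame, cultivar: str
) -> pd.DataFrame:
    """Normalized modification signal of genes grouped by expression bin."""
    sub = rpkms[rpkms["cultivar"] == cultivar]
    rows = []
    for b in EXPRESSION_BINS:
        vals = [
            signal_per_gene[g]
            for g in sub.loc[sub["bin"] == b, "gene_id"]
            if g in signal_per_gene
        ]
        s = pd.Series(vals, dtype=float)
        rows.append(
            {
                "bin": b, "n": len(vals),
                "mean_signal": float(s.mean()) if len(vals) else float("nan"),
                "median_signal": float(s.median()) if len(vals) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
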