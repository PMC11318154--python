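"""SNP-based allele partitioning of hybrid reads, allele-specific histone
modification (ASHM) and allele-specific expression (ASE).

In an F1 hybrid of two homozygous parents, every diagnostic SNP (parents
homozygous for different bases) identifies the parental origin of any read
covering it. Reads voting unanimously for one parent are assigned to it;
reads with conflicting or non-parental bases — or covering no usable SNP —
are *ambiguous*, so the maternal/paternal/ambiguous tallies partition all
reads overlapping a gene's counting region.

ASHM classification uses the maternal fraction of informative reads: genes
with more than 9 informative reads are classified as biallelic (BAHM) when
the fraction lies in [1/3, 2/3] (allelic difference below 2-fold) and
allele-specific otherwise, toward the parent with the higher level.

ASE uses an exact two-sided binomial test on pooled maternal/paternal read
counts with |log2(M/P)| >= 1, P < 0.05, and the same direction of bias in
every replicate.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomeIntervalIndex
from .io import parse_cigar
from .stats import binomial_two_sided, chi_squared_2x2, percent, spearman
from .types import AlignedRead, ASERecord, ASHMRecord, GeneModel, SNPRecord

log = logging.getLogger(__name__)

MIN_INFORMATIVE_READS = 10  # "more than 9 reads containing SNP sites"
BAHM_LOW = Fraction(1, 3)
BAHM_HIGH = Fraction(2, 3)
ASE_LOG2FC_MIN = 1.0
ASE_PVALUE_MAX = 0.05


@dataclass
class AlleleCount:
    """Per-gene allele-partitioned read tallies for one assay (and replicate)."""

    gene_id: str
    assay: str
    replicate: int | None
    maternal_reads: int = 0
    paternal_reads: int = 0
    ambiguous_reads: int = 0

    @property
    def informative(self) -> int:
        return self.maternal_reads + self.paternal_reads

    @property
    def total(self) -> int:
        return self.informative + self.ambiguous_reads


def _aligned_blocks(pos: int, cigar: str) -> list[tuple[int, int, int]]:
    """(ref_start, ref_end, read_offset) blocks where read bases align to reference."""
    blocks = []
    ref, idx = pos, 0
    for n, op in parse_cigar(cigar):
        if op in "M=X":
            blocks.append((ref, ref + n, idx))
            ref += n
            idx += n
        elif op in "DN":
            ref += n
        elif op in "IS":
            idx += n
    return blocks


def read_base_at(read: AlignedRead, ref_pos: int) -> str | None:
    """Read base aligned to a reference position; None under D/N/S or outside."""
    for rs, re_, off in _aligned_blocks(read.pos, read.cigar):
        if rs <= ref_pos < re_:
            return read.seq[off + (ref_pos - rs)]
    return None


def cds_snps(snps: Iterable[SNPRecord], genes: Sequence[GeneModel]) -> list[SNPRecord]:
    """Restrict a SNP list to positions inside any gene's CDS."""
    cds_index = GenomeIntervalIndex()
    for g in genes:
        for s, e in g.cds:
            cds_index.add(g.chrom, s, e, g.gene_id)
    return [s for s in snps if cds_index.overlaps_point(s.chrom, s.pos)]


def partition_reads(
    reads: Iterable[AlignedRead],
    snps: Sequence[SNPRecord],
    genes: Sequence[GeneModel],
    count_region: str = "gene-body",
    assay: str = "chip",
    replicate: int | None = None,
    restrict_snps_to_cds: bool = True,
) -> list[AlleleCount]:
    """Partition hybrid reads into parental origins and tally them per gene.

    The SNP list is restricted to CDS positions (where diagnostic SNPs were
    screened) while reads are counted over each gene's ``count_region``
    ('gene-body' or 'CDS'); a read anywhere in the counting region that covers
    a CDS SNP is informative.
    """
    if count_region not in ("gene-body", "CDS"):
        raise ValueError(f"count_region must be 'gene-body' or 'CDS', got {count_region!r}")
    usable = cds_snps(snps, genes) if restrict_snps_to_cds else list(snps)
    snp_pos: dict[str, np.ndarray] = {}
    snp_base: dict[tuple[str, int], tuple[str, str]] = {}
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for s in usable:
        by_chrom[s.chrom].append(s.pos)
        snp_base[(s.chrom, s.pos)] = (s.maternal_base, s.paternal_base)
    for chrom, positions in by_chrom.items():
        snp_pos[chrom] = np.asarray(sorted(set(positions)), dtype=np.int64)

    gene_index = GenomeIntervalIndex()
    for g in genes:
        intervals = g.cds if count_region == "CDS" else [(g.start, g.end)]
        for s, e in intervals:
            gene_index.add(g.chrom, s, e, g.gene_id)

    tallies: dict[str, AlleleCount] = {
        g.gene_id: AlleleCount(g.gene_id, assay, replicate) for g in genes
    }
    for read in reads:
        blocks = _aligned_blocks(read.pos, read.cigar)
        if not blocks:
            continue
        ref_end = blocks[-1][1]
        hit_genes = set(gene_index.overlap_query(read.chrom, read.pos, ref_end))
        if not hit_genes:
            continue
        votes = set()
        positions = snp_pos.get(read.chrom)
        if positions is not None:
            lo = int(np.searchsorted(positions, read.pos, side="left"))
            hi = int(np.searchsorted(positions, ref_end, side="left"))
            for p in positions[lo:hi]:
                base = read_base_at(read, int(p))
                if base is None:
                    continue  # SNP under a deletion or splice gap: no vote
                mat, pat = snp_base[(read.chrom, int(p))]
                if base == mat:
                    votes.add("maternal")
                elif base == pat:
                    votes.add("paternal")
                else:
                    votes.add("neither")
        if votes == {"maternal"}:
            field = "maternal_reads"
        elif votes == {"paternal"}:
            field = "paternal_reads"
        else:  # no vote, conflict, or non-parental base
            field = "ambiguous_reads"
        for gid in hit_genes:
            setattr(tallies[gid], field, getattr(tallies[gid], field) + 1)
    return [tallies[g.gene_id] for g in genes]


def classify_ashm(
    count: AlleleCount,
    mark: str,
    min_informative: int = MIN_INFORMATIVE_READS,
    low: Fraction | float = BAHM_LOW,
    high: Fraction | float = BAHM_HIGH,
) -> ASHMRecord:
    """Classify a gene's allelic histone-modification state in the hybrid.

    Boundary ratios exactly at 1/3 or 2/3 are biallelic (the bounds are
    inclusive); genes at or below 9 informative reads are filtered.
    """
    n = count.informative
    if n < min_informative:
        return ASHMRecord(count.gene_id, mark, None if n == 0 else count.maternal_reads / n, n, "filtered")
    ratio = Fraction(count.maternal_reads, n)
    low, high = Fraction(low), Fraction(high)
    if ratio > high:
        klass = "ASHM-maternal"
    elif ratio < low:
        klass = "ASHM-paternal"
    else:
        klass = "BAHM"
    return ASHMRecord(count.gene_id, mark, float(ratio), n, klass)


def summarize_allele_classes(class_counts: Mapping[str, int]) -> dict:
    """Class counts plus the ASHM percentage at the printed precision.

    ``class_counts`` maps {BAHM, ASHM-maternal, ASHM-paternal} to gene counts
    (filtered genes are not part of the analyzable universe).
    """
    n_ashm = class_counts.get("ASHM-maternal", 0) + class_counts.get("ASHM-paternal", 0)
    n_total = n_ashm + class_counts.get("BAHM", 0)
    out = {
        "n_analyzable": n_total,
        "n_ashm": n_ashm,
        "n_bahm": class_counts.get("BAHM", 0),
        "n_ashm_maternal": class_counts.get("ASHM-maternal", 0),
        "n_ashm_paternal": class_counts.get("ASHM-paternal", 0),
    }
    if n_total:
        out["ashm_percent"] = percent(n_ashm, n_total, 1)
        out["bahm_percent"] = percent(out["n_bahm"], n_total, 1)
    return out


def call_ase(
    replicate_counts: Sequence[tuple[int, int]],
    gene_id: str,
    log2fc_min: float = ASE_LOG2FC_MIN,
    pvalue_max: float = ASE_PVALUE_MAX,
) -> ASERecord | None:
    """Allele-specific expression call from per-replicate (maternal, paternal) counts.

    Pooled counts drive the exact binomial test and the pseudocounted
    log2(M/P); the bias label additionally requires the same strict direction
    in every replicate. Returns None (logged) when a replicate has no
    informative reads.
    """
    if len(replicate_counts) < 2:
        raise ValueError("ASE requires >= 2 replicates")
    if any(m + p == 0 for m, p in replicate_counts):
        log.info("gene %s: replicate with zero informative reads; excluded", gene_id)
        return None
    pooled_m = sum(m for m, _ in replicate_counts)
    pooled_p = sum(p for _, p in replicate_counts)
    pvalue = binomial_two_sided(pooled_m, pooled_m + pooled_p)
    log2_mp = math.log2((pooled_m + 1) / (pooled_p + 1))
    signs = {np.sign(m - p) for m, p in replicate_counts}
    bias = "none"
    if abs(log2_mp) >= log2fc_min and pvalue < pvalue_max:
        if signs == {1} and log2_mp > 0:
            bias = "maternal"
        elif signs == {-1} and log2_mp < 0:
            bias = "paternal"
    return ASERecord(gene_id, list(replicate_counts), log2_mp, pvalue, bias)


def ashm_ase_concordance(
    ashm: Sequence[ASHMRecord], ase: Sequence[ASERecord]
) -> dict[str, int]:
    """Cross-tabulate ASHM direction against ASE bias per gene.

    Concordant: ASHM and ASE favour the same parent. Genes with only one of
    the two signals (including biallelic genes with an ASE bias) fall into
    the ashm-only / ase-only classes.
    """
    ashm_dir = {r.gene_id: r.klass for r in ashm if r.klass.startswith("ASHM")}
    ase_dir = {r.gene_id: r.bias for r in ase if r.bias != "none"}
    out = {"concordant": 0, "discordant": 0, "ashm-only": 0, "ase-only": 0}
    for gid, klass in ashm_dir.items():
        bias = ase_dir.get(gid)
        if bias is None:
            out["ashm-only"] += 1
        elif klass == f"ASHM-{bias}":
            out["concordant"] += 1
        else:
            out["discordant"] += 1
    out["ase-only"] = sum(1 for gid in ase_dir if gid not in ashm_dir)
    return out


def ashm_dhm_association(
    ashm: Sequence[ASHMRecord], dhm_hp_genes: set[str], background: set[str]
) -> dict:
    """Enrichment of ASHM among hybrid-parent DHM genes vs the genomic average.

    2x2 chi-squared (1 df, no continuity correction) on {ASHM, BAHM} x
    {in DHM_HP, not}; all genes must come from the same universe.
    """
    if not dhm_hp_genes <= background:
        raise ValueError("DHM_HP genes must be a subset of the background universe")
    classified = [r for r in ashm if r.klass != "filtered" and r.gene_id in background]
    table = np.zeros((2, 2), dtype=int)
    for r in classified:
        i = 0 if r.klass.startswith("ASHM") else 1
        j = 0 if r.gene_id in dhm_hp_genes else 1
        table[i, j] += 1
    stat, pvalue = chi_squared_2x2(table)
    col = table.sum(axis=0)
    return {
        "table": table.tolist(),
        "ashm_fraction_in_dhm_hp": table[0, 0] / col[0] if col[0] else float("nan"),
        "ashm_fraction_elsewhere": table[0, 1] / col[1] if col[1] else float("nan"),
        "chi2": stat,
        "pvalue": pvalue,
    }


def dhm_ashm_correlation(
    parental_log2fc: Mapping[str, float], allele_ratio: Mapping[str, float]
) -> float:
    """Spearman correlation between parental modification differences and the
    hybrid's allelic ratio over the shared genes."""
    shared = sorted(set(parental_log2fc) & set(allele_ratio))
    if len(shared) < 3:
        raise ValueError("need >= 3 paired genes")
    return spearman(
        [parental_log2fc[g] for g in shared], [allele_ratio[g] for g in shared]
    )
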