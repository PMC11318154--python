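"""Cytosine methylation: site levels, CG strand combining, site calling,
gene-level weighted levels with five-class binning, and DMC/DMR calling.

The methylation level of a site is the fraction of bisulfite-converted reads
still carrying C. Symmetric CG sites are combined across strands (plus-strand
C at p pairs with the minus-strand C at p+1). A site is *methylated* when its
level exceeds the bisulfite non-conversion noise floor by a one-sided
binomial test, BH-corrected across sites.

Gene-level methylation is the weighted level over sites in the gene body
(sum of mC reads / sum of total reads), binned into five classes:
unmethylated [0,0.1), low [0.1,0.4), moderate [0.4,0.6], high (0.6,0.9],
full (0.9,1].

A differentially methylated cytosine (DMC) between two samples requires a
level difference of at least 0.4 (CG) or 0.2 (CHG/CHH) and a two-sided
Fisher's exact P < 0.05 on the read counts. A DMR chains >= 3 same-direction
DMCs of one context with inter-site gaps <= max_gap.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats as sps

from .stats import bh_adjust, binomial_upper_tail
from .types import DMR, GeneMethylation, GeneModel, SiteMethylation

log = logging.getLogger(__name__)

DMC_DIFF_THRESHOLDS = {"CG": 0.4, "CHG": 0.2, "CHH": 0.2}
DMC_PVALUE_MAX = 0.05
DMR_MIN_DMCS = 3
DMR_MAX_GAP = 200
SITE_ERROR_RATE = 0.005  # bisulfite non-conversion / sequencing noise floor
SITE_FDR = 0.05

METHYLATION_BINS = ("unmethylated", "low", "moderate", "high", "full")


def assign_methylation_bin(level: float) -> str:
    """Five-class bin; total on [0, 1] with the stated boundary conventions."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"methylation level outside [0,1]: {level}")
    if level < 0.1:
        return "unmethylated"
    if level < 0.4:
        return "low"
    if level <= 0.6:
        return "moderate"
    if level <= 0.9:
        return "high"
    return "full"


def combine_cg_strands(sites: Iterable[SiteMethylation]) -> list[SiteMethylation]:
    """Sum read counts of symmetric CG pairs; everything else passes through.

    A plus-strand CG at p merges with a minus-strand CG at p+1 into one
    record at p; unpaired CG sites are kept unchanged.
    """
    sites = sorted(sites, key=lambda s: (s.chrom, s.pos, s.strand))
    minus = {
        (s.chrom, s.pos): i
        for i, s in enumerate(sites)
        if s.context == "CG" and s.strand == "-"
    }
    out: list[SiteMethylation] = []
    consumed: set[int] = set()
    for i, s in enumerate(sites):
        if i in consumed:
            continue
        if s.context == "CG" and s.strand == "+":
            j = minus.get((s.chrom, s.pos + 1))
            if j is not None and j not in consumed:
                mate = sites[j]
                out.append(
                    SiteMethylation(
                        s.chrom, s.pos, "+", "CG",
                        s.mc_reads + mate.mc_reads, s.total_reads + mate.total_reads,
                    )
                )
                consumed.update((i, j))
                continue
        out.append(s)
        consumed.add(i)
    return sorted(out, key=lambda s: (s.chrom, s.pos, s.strand))


def site_binomial_test(site: SiteMethylation, error_rate: float = SITE_ERROR_RATE) -> float:
    """One-sided upper-tail binomial P(X >= mC | n, error_rate)."""
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    if site.total_reads == 0:
        raise ValueError("site with zero coverage is undefined; skip it")
    return binomial_upper_tail(site.mc_reads, site.total_reads, error_rate)


def call_methylated_sites(
    sites: Sequence[SiteMethylation],
    error_rate: float = SITE_ERROR_RATE,
    fdr: float = SITE_FDR,
) -> list[bool]:
    """Per-site methylated flags: binomial above noise, BH across sites."""
    covered = [s for s in sites if s.total_reads > 0]
    pvals = [site_binomial_test(s, error_rate) for s in covered]
    flags_covered = bh_adjust(pvals) < fdr if covered else []
    flags_iter = iter(flags_covered)
    return [bool(next(flags_iter)) if s.total_reads > 0 else False for s in sites]


def gene_weighted_level(
    gene: GeneModel,
    sites: Sequence[SiteMethylation],
    cultivar: str = "",
    context: str | None = None,
) -> GeneMethylation:
    """Weighted methylation level of a gene body, with five-class bin.

    ``context=None`` combines all contexts; per-context levels are reported
    alongside either way. Genes with no covered site get the 'no-data'
    sentinel and are excluded from cross-tabulations.
    """
    in_body = [
        s for s in sites
        if s.chrom == gene.chrom and gene.start <= s.pos < gene.end and s.total_reads > 0
    ]
    ctx_levels: dict[str, float | None] = {}
    for ctx in ("CG", "CHG", "CHH"):
        sub = [s for s in in_body if s.context == ctx]
        mc, tot = sum(s.mc_reads for s in sub), sum(s.total_reads for s in sub)
        ctx_levels[ctx] = mc / tot if tot else None
    used = in_body if context is None else [s for s in in_body if s.context == context]
    mc, tot = sum(s.mc_reads for s in used), sum(s.total_reads for s in used)
    if tot == 0:
        return GeneMethylation(gene.gene_id, cultivar, None, ctx_levels, "no-data")
    level = mc / tot
    return GeneMethylation(gene.gene_id, cultivar, level, ctx_levels, assign_methylation_bin(level))


@dataclass
class DMC:
    chrom: str
    pos: int
    context: str
    level_a: float
    level_b: float
    pvalue: float

    @property
    def diff(self) -> float:
        return self.level_a - self.level_b

    @property
    def direction(self) -> int:
        return 1 if self.diff > 0 else -1


def call_dmcs(
    sites_a: Sequence[SiteMethylation],
    sites_b: Sequence[SiteMethylation],
    context: str,
    diff_threshold: float | None = None,
    pvalue_max: float = DMC_PVALUE_MAX,
) -> list[DMC]:
    """Differentially methylated cytosines between two samples, one context.

    Sites are matched by (chrom, pos); positions covered in only one sample
    are skipped. The level-difference threshold is applied before the Fisher
    test, so the test runs only where it can matter.
    """
    if diff_threshold is None:
        diff_threshold = DMC_DIFF_THRESHOLDS[context]
    index_b = {
        (s.chrom, s.pos): s for s in sites_b if s.context == context and s.total_reads > 0
    }
    dmcs = []
    for sa in sites_a:
        if sa.context != context or sa.total_reads == 0:
            continue
        sb = index_b.get((sa.chrom, sa.pos))
        if sb is None:
            continue
        diff = sa.level - sb.level
        if abs(diff) < diff_threshold:
            continue
        _, pvalue = sps.fisher_exact(
            [[sa.mc_reads, sa.total_reads - sa.mc_reads], [sb.mc_reads, sb.total_reads - sb.mc_reads]],
            alternative="two-sided",
        )
        if pvalue < pvalue_max:
            dmcs.append(DMC(sa.chrom, sa.pos, context, sa.level, sb.level, float(pvalue)))
    return sorted(dmcs, key=lambda d: (d.chrom, d.pos))


def call_dmrs(dmcs: Sequence[DMC], max_gap: int = DMR_MAX_GAP, min_dmcs: int = DMR_MIN_DMCS) -> list[DMR]:
    """Greedy chaining of same-direction DMCs into regions.

    Consecutive DMCs of one chromosome and context chain while the inter-site
    gap is <= max_gap and the direction is unchanged; an intervening DMC of
    the opposite direction breaks the chain. Chains of >= min_dmcs sites
    become DMRs spanning first to last member cytosine.
    """
    by_key: dict[tuple[str, str], list[DMC]] = defaultdict(list)
    for d in sorted(dmcs, key=lambda d: (d.chrom, d.pos)):
        by_key[(d.chrom, d.context)].append(d)
    dmrs = []
    for (chrom, context), members in sorted(by_key.items()):
        chain: list[DMC] = []

        def close(chain: list[DMC]) -> None:
            if len(chain) >= min_dmcs:
                dmrs.append(
                    DMR(
                        chrom, chain[0].pos, chain[-1].pos + 1, context,
                        len(chain),
                        sum(c.diff for c in chain) / len(chain),
                        chain[0].direction,
                    )
                )

        for d in members:
            if chain and (d.pos - chain[-1].pos > max_gap or d.direction != chain[-1].direction):
                close(chain)
                chain = []
            chain.append(d)
        close(chain)
    return sorted(dmrs, key=lambda r: (r.chrom, r.start, r.end))


def genes_overlapping_dmrs(genes: Sequence[GeneModel], dmrs: Sequence[DMR]) -> set[str]:
    from .intervals import GenomeIntervalIndex

    idx = GenomeIntervalIndex()
    for d in dmrs:
        idx.add(d.chrom, d.start, d.end, (d.start, d.end))
    return {
        g.gene_id for g in genes if idx.overlap_query(g.chrom, g.start, g.end)
    }


def write_dmr_bed(dmrs: Sequence[DMR], path) -> None:
    """BED with score = mean level difference x 1000 (integer)."""
    with open(path, "w") as fh:
        for i, d in enumerate(dmrs):
            score = int(round(abs(d.mean_diff) * 1000))
            strand = "+" if d.direction > 0 else "-"
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tdmr_{d.context}_{i}\t{score}\t{strand}\n")


def methylation_bin_table(
    gene_bins: Mapping[str, str], target_genes: set[str]
) -> dict[str, int]:
    """Counts of target genes per methylation bin (no-data excluded)."""
    if not target_genes:
        raise ValueError("empty target gene set")
    counts = {b: 0 for b in METHYLATION_BINS}
    for gid in target_genes:
        b = gene_bins.get(gid, "no-data")
        if b in counts:
            counts[b] += 1
    return counts
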