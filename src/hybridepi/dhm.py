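"""Consensus regions, peak-to-gene annotation and differential histone
modification (DHM) statistics.

A *consensus region* is the merged union of overlapping peaks of one mark
across all cultivars: the unit on which modification levels are compared.
Regions are annotated to genes through their midpoint, with the activating
promoter-proximal geometry in mind: a midpoint falling in an overlapping
promoter-TSS window wins over TTS, exon and intron.

A DHM call between two cultivars uses Fisher's exact test on replicate-pooled
counts and requires |log2FC| >= 1 and P < 0.01 (raw, no FDR); *hyper* means a
higher level in the first contrast member, *hypo* lower.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomeIntervalIndex, merge_intervals
from .io import CountTable
from .stats import fisher_count_test
from .types import CONTRASTS, ConsensusRegion, DHMRecord, GeneModel, Peak

log = logging.getLogger(__name__)

DHM_LOG2FC_MIN = 1.0
DHM_PVALUE_MAX = 0.01

#: annotation priority when windows overlap (highest first)
_FEATURE_PRIORITY = ("promoter-TSS", "TTS", "exon", "intron")


def build_consensus(peaks: Sequence[Peak], mark: str) -> list[ConsensusRegion]:
    """Merge peaks of one mark across cultivars into consensus regions.

    Any >= 1 bp overlap (or book-ending) joins peaks into the same region.
    Region fold enrichment is the mean over member peaks.
    """
    peaks = [p for p in peaks if p.mark == mark]
    if any(p.mark != mark for p in peaks):
        raise ValueError("peaks must all carry the requested mark")
    by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)
    regions: list[ConsensusRegion] = []
    for chrom in sorted(by_chrom):
        merged = merge_intervals([(p.start, p.end) for p in by_chrom[chrom]])
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        for start, end in merged:
            members = [p for p in chrom_peaks if p.start < end and start < p.end]
            regions.append(
                ConsensusRegion(
                    region_id=f"{mark}:{chrom}:{start}-{end}",
                    chrom=chrom, start=start, end=end, mark=mark,
                    contributors=frozenset(p.cultivar for p in members),
                    fold_enrichment=statistics.fmean(p.fold_enrichment for p in members),
                    members=members,
                )
            )
    return regions


class FeatureIndex:
    """Point-to-feature annotator over a set of gene models."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._indexes: dict[str, GenomeIntervalIndex] = {f: GenomeIntervalIndex() for f in _FEATURE_PRIORITY}
        self._genes: dict[str, GeneModel] = {}
        for g in sorted(genes, key=lambda g: g.gene_id):
            self._genes[g.gene_id] = g
            ps, pe = g.promoter_window()
            self._indexes["promoter-TSS"].add(g.chrom, ps, pe, g.gene_id)
            ts, te = g.tts_window()
            self._indexes["TTS"].add(g.chrom, ts, te, g.gene_id)
            for s, e in g.exons:
                self._indexes["exon"].add(g.chrom, s, e, g.gene_id)
            for s, e in g.introns():
                self._indexes["intron"].add(g.chrom, s, e, g.gene_id)

    def gene(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def annotate_point(self, chrom: str, pos: int) -> tuple[str | None, str]:
        """(gene_id, feature label) for a genomic point; intergenic -> (None, ...)."""
        for feature in _FEATURE_PRIORITY:
            hits = self._indexes[feature].overlaps_point(chrom, pos)
            if hits:
                anchor = {
                    "promoter-TSS": lambda g: abs(pos - self._genes[g].tss),
                    "TTS": lambda g: abs(pos - self._genes[g].tts),
                }.get(feature, lambda g: 0)
                winner = min(hits, key=lambda g: (anchor(g), g))
                return winner, feature
        return None, "intergenic"


def annotate_region(region: ConsensusRegion, index: FeatureIndex) -> ConsensusRegion:
    """Annotate a region in place by its midpoint; returns the region."""
    region.gene_id, region.feature = index.annotate_point(region.chrom, region.midpoint)
    return region


def annotate_regions(regions: Iterable[ConsensusRegion], genes: Iterable[GeneModel]) -> list[ConsensusRegion]:
    index = FeatureIndex(genes)
    return [annotate_region(r, index) for r in regions]


def _region_counts(region: ConsensusRegion, counts: CountTable, cultivar: str) -> tuple[int, int] | None:
    pooled, lib = counts.pooled(cultivar)
    key = region.region_id if region.region_id in pooled.index else region.gene_id
    if key is None or key not in pooled.index:
        return None
    return int(pooled[key]), lib


def call_dhm(
    regions: Sequence[ConsensusRegion],
    counts: CountTable,
    contrast: str,
    log2fc_min: float = DHM_LOG2FC_MIN,
    pvalue_max: float = DHM_PVALUE_MAX,
) -> list[DHMRecord]:
    """Differential-modification call for every region with counts on both sides."""
    a, b = CONTRASTS[contrast]
    records = []
    for region in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        ca, cb = _region_counts(region, counts, a), _region_counts(region, counts, b)
        if ca is None or cb is None:
            log.debug("region %s lacks counts; skipped", region.region_id)
            continue
        log2fc, pvalue = fisher_count_test(ca[0], ca[1], cb[0], cb[1])
        if pvalue < pvalue_max and log2fc >= log2fc_min:
            status = "hyper"
        elif pvalue < pvalue_max and log2fc <= -log2fc_min:
            status = "hypo"
        else:
            status = "ns"
        records.append(DHMRecord(region.region_id, region.gene_id, contrast, log2fc, pvalue, status))
    return records


def inherited_direction(hx_contrast: str, hx_status: str) -> str:
    """Parental DHM status implying inheritance of a hybrid-parent DHM.

    H>M is inherited from P>M (PP hypo); H<M from P<M (PP hyper);
    H>P from M>P (PP hyper); H<P from M<P (PP hypo).
    """
    if hx_contrast == "HM":
        return "hypo" if hx_status == "hyper" else "hyper"
    if hx_contrast == "HP":
        return hx_status
    raise ValueError(f"inheritance is defined for HM/HP contrasts, not {hx_contrast!r}")


def attribute_origin(
    dhm_hx: Sequence[DHMRecord],
    dhm_pp: Sequence[DHMRecord],
    exclude: set[str] | None = None,
) -> tuple[list[DHMRecord], dict]:
    """Attribute each significant hybrid-parent DHM to parental origin.

    A DHM_HP is *inherited* when the same region shows the matching parental
    difference (see :func:`inherited_direction`), *novel* otherwise —
    including regions absent from the parental call set. ``exclude`` drops
    regions (e.g. those with conflicting H-vs-M / H-vs-P directions) from the
    summary fractions only; their per-record pattern is still set.
    """
    pp_status = {r.region_id: r.status for r in dhm_pp}
    exclude = exclude or set()
    summary: dict = {"by_direction": {}, "overall": {}}
    tallies: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])  # inherited, novel
    out = []
    for rec in dhm_hx:
        if rec.status == "ns":
            rec.pattern = None
            out.append(rec)
            continue
        want = inherited_direction(rec.contrast, rec.status)
        got = pp_status.get(rec.region_id)
        if got is None:
            log.debug("region %s absent from parental calls; treated as novel", rec.region_id)
        rec.pattern = "inherited" if got == want else "novel"
        out.append(rec)
        if rec.region_id not in exclude:
            tallies[(rec.contrast, rec.status)][0 if rec.pattern == "inherited" else 1] += 1
    total_inh = total_nov = 0
    for key, (inh, nov) in sorted(tallies.items()):
        n = inh + nov
        summary["by_direction"]["{}:{}".format(*key)] = {
            "inherited": inh, "novel": nov,
            "fraction_inherited": inh / n if n else 0.0,
        }
        total_inh += inh
        total_nov += nov
    n = total_inh + total_nov
    summary["overall"] = {
        "inherited": total_inh, "novel": total_nov,
        "fraction_inherited": total_inh / n if n else 0.0,
        "fraction_novel": total_nov / n if n else 1.0,
    }
    return out, summary


def conflicting_regions(dhm_hm: Sequence[DHMRecord], dhm_hp: Sequence[DHMRecord]) -> set[str]:
    """Regions whose H-vs-M and H-vs-P calls disagree in sign (both significant)."""
    hm = {r.region_id: r.status for r in dhm_hm if r.status != "ns"}
    out = set()
    for r in dhm_hp:
        if r.status != "ns" and hm.get(r.region_id) not in (None, r.status):
            out.add(r.region_id)
    return out


def feature_enrichment_summary(regions: Sequence[ConsensusRegion]) -> pd.DataFrame:
    """Fold-enrichment distribution per feature class and cultivar.

    Per cultivar, a region contributes the mean fold enrichment of that
    cultivar's member peaks; features with no regions get n=0 and NaN stats.
    """
    rows = []
    features = list(_FEATURE_PRIORITY) + ["intergenic"]
    cultivars = sorted({p.cultivar for r in regions for p in r.members})
    for cultivar in cultivars:
        by_feature: dict[str, list[float]] = defaultdict(list)
        for r in regions:
            fes = [p.fold_enrichment for p in r.members if p.cultivar == cultivar]
            if fes:
                by_feature[r.feature].append(statistics.fmean(fes))
        for feature in features:
            vals = by_feature.get(feature, [])
            rows.append(
                {
                    "cultivar": cultivar, "feature": feature, "n": len(vals),
                    "mean_fe": statistics.fmean(vals) if vals else float("nan"),
                    "median_fe": statistics.median(vals) if vals else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def target_set_overlap(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every region of the Venn partition of the named sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    partition: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            partition[combo] = len(inside - outside)
    return partition
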