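"""Readers and writers for the standard text formats the pipeline consumes.

Conventions at the boundary:

* GFF3 is 1-based inclusive on disk, converted to 0-based half-open in memory.
* BED (6 and 12 column) is already 0-based half-open.
* SAM text is accepted with or without a header; only mapped records are kept.
* Diagnostic SNPs come either as a 4-column TSV (1-based positions) or as a
  VCF subset with two sample genotype columns (maternal sample first).
* Per-cytosine methylation TSVs use 1-based positions.

All writers emit deterministic column and line order so that identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .types import AlignedRead, GeneModel, Peak, SiteMethylation, SNPRecord

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_SUPPORTED_CIGAR_OPS = set("MIDNS=X")
LIBRARY_SIZE_ROW = "library_size"


class FormatError(ValueError):
    """Malformed input file; message names the file and line."""


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (.gff/.gff3) or BED12 (.bed)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    if path.suffix.lower() == ".bed":
        return _read_bed12(path)
    raise FormatError(f"{path}: unsupported gene-model format (expect .gff3 or .bed)")


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    # cheap pre-scan so malformed lines are reported with their line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise FormatError(f"{path}:{lineno}: invalid 1-based interval {start}-{end}")

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [(f.start - 1, f.end) for f in db.children(g, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(g, featuretype="CDS")]
        if not exons:
            log.warning("%s: gene %s has no exons; using gene interval as single exon", path, g.id)
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, strand=g.strand,
                start=g.start - 1, end=g.end, exons=sorted(set(exons)), cds=sorted(set(cds)),
            )
        )
    return genes


def write_gene_models_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\thybridepi\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\thybridepi\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\thybridepi\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\thybridepi\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 requires 12 fields, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed BED12 fields") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount does not match block lists")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            cds = []
            if thick_end > thick_start:
                for s, e in exons:
                    cs, ce = max(s, thick_start), min(e, thick_end)
                    if cs < ce:
                        cds.append((cs, ce))
            genes.append(GeneModel(name, chrom, strand, start, end, exons=exons, cds=cds))
    return genes


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            thick = (g.cds[0][0], g.cds[-1][1]) if g.cds else (g.start, g.start)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{thick[0]}\t{thick[1]}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# peaks (BED6+: col7 fold_enrichment, col8 pvalue)


def read_peaks_bed(path: str | Path, mark: str, cultivar: str) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise FormatError(f"{path}:{lineno}: peak BED requires >=7 fields")
            try:
                peaks.append(
                    Peak(
                        chrom=f[0], start=int(f[1]), end=int(f[2]),
                        mark=mark, cultivar=cultivar,
                        fold_enrichment=float(f[6]),
                        pvalue=float(f[7]) if len(f) > 7 else 1.0,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed peak line") from exc
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t0\t.\t"
                f"{p.fold_enrichment:.4f}\t{p.pvalue:.4g}\n"
            )


# ---------------------------------------------------------------------------
# diagnostic SNPs


def read_snps(path: str | Path) -> list[SNPRecord]:
    """Read diagnostic SNPs from TSV (chrom, pos1based, maternal, paternal) or VCF."""
    path = Path(path)
    if path.suffix.lower() == ".vcf" or str(path).endswith(".vcf.gz"):
        return _read_snps_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "maternal_base", "paternal_base"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: SNP TSV needs columns {sorted(required)}")
    return [
        SNPRecord(r.chrom, int(r.pos) - 1, r.maternal_base, r.paternal_base)
        for r in df.itertuples()
    ]


def _read_snps_vcf(path: Path) -> list[SNPRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) < 2:
        raise FormatError(f"{path}: VCF needs two sample columns (maternal, paternal)")
    snps = []
    for v in vcf:
        alleles = [v.REF] + v.ALT
        gts = v.genotypes  # [allele1, allele2, phased]
        m, p = gts[0], gts[1]
        if m[0] != m[1] or p[0] != p[1] or m[0] < 0 or p[0] < 0:
            log.warning("%s: %s:%d not homozygous in both parents; skipped", path, v.CHROM, v.POS)
            continue
        mb, pb = alleles[m[0]], alleles[p[0]]
        if mb == pb or len(mb) != 1 or len(pb) != 1:
            log.warning("%s: %s:%d not a diagnostic SNP; skipped", path, v.CHROM, v.POS)
            continue
        snps.append(SNPRecord(v.CHROM, v.POS - 1, mb, pb))
    return snps


def write_snps_tsv(snps: Iterable[SNPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tmaternal_base\tpaternal_base\n")
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.maternal_base}\t{s.paternal_base}\n")


# ---------------------------------------------------------------------------
# SAM


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string; H and P operations are rejected."""
    if cigar == "*" or not cigar:
        raise FormatError("missing CIGAR")
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    out = []
    for n, op in ops:
        if op not in _SUPPORTED_CIGAR_OPS:
            raise FormatError(f"unsupported CIGAR op {op!r} in {cigar!r} (H/P not handled)")
        out.append((int(n), op))
    return out


def cigar_reference_span(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MDN=X")


def iter_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Stream mapped records from a SAM text file (header optional)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno}: SAM record needs >=10 fields")
            if f[2] == "*" or f[5] == "*":
                continue  # unmapped
            try:
                read = AlignedRead(read_id=f[0], chrom=f[2], pos=int(f[3]) - 1, cigar=f[5], seq=f[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed SAM record") from exc
            qlen = sum(n for n, op in parse_cigar(read.cigar) if op in "MIS=X")
            if read.seq != "*" and len(read.seq) != qlen:
                raise FormatError(f"{path}:{lineno}: SEQ length inconsistent with CIGAR")
            yield read


def read_sam(path: str | Path) -> list[AlignedRead]:
    return list(iter_sam(path))


def write_sam(
    reads: Iterable[AlignedRead], path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(chrom_lengths or {}):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}\n")
        for r in reads:
            fh.write(f"{r.read_id}\t0\t{r.chrom}\t{r.pos + 1}\t255\t{r.cigar}\t*\t0\t0\t{r.seq}\t*\n")


# ---------------------------------------------------------------------------
# count tables


@dataclass
class CountTable:
    """Per-region (or per-gene) integer read counts with per-sample library sizes.

    Sample names encode cultivar and replicate as ``<cultivar>_rep<i>``.
    """

    counts: pd.DataFrame  # index: region/gene id; columns: samples
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(int)
        self.library_sizes = self.library_sizes.astype(int).reindex(self.counts.columns)
        short = self.library_sizes < self.counts.sum(axis=0)
        if short.any():
            bad = ", ".join(self.library_sizes.index[short])
            raise ValueError(f"library size smaller than column count sum for: {bad}")

    def samples_for(self, cultivar: str) -> list[str]:
        return [c for c in self.counts.columns if c == cultivar or c.startswith(f"{cultivar}_")]

    def pooled(self, cultivar: str) -> tuple[pd.Series, int]:
        """Replicate-pooled counts and library size for one cultivar."""
        cols = self.samples_for(cultivar)
        if not cols:
            raise KeyError(f"no samples for cultivar {cultivar!r}")
        return self.counts[cols].sum(axis=1), int(self.library_sizes[cols].sum())


def read_count_table(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if LIBRARY_SIZE_ROW not in df.index:
        raise FormatError(f"{path}: count table needs a '{LIBRARY_SIZE_ROW}' row")
    lib = df.loc[LIBRARY_SIZE_ROW]
    counts = df.drop(index=LIBRARY_SIZE_ROW)
    return CountTable(counts=counts, library_sizes=lib)


def write_count_table(table: CountTable, path: str | Path) -> None:
    out = pd.concat([table.counts, table.library_sizes.to_frame(LIBRARY_SIZE_ROW).T])
    out = out.sort_index(key=lambda idx: idx != LIBRARY_SIZE_ROW, kind="stable")
    # library_size row first, then regions in sorted order
    body = out.drop(index=LIBRARY_SIZE_ROW).sort_index()
    final = pd.concat([out.loc[[LIBRARY_SIZE_ROW]], body])
    final.index.name = "region_id"
    final.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# per-cytosine methylation


def read_methylation_tsv(path: str | Path) -> list[SiteMethylation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "context": str})
    required = {"chrom", "pos", "strand", "context", "mc_reads", "total_reads"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: methylation TSV needs columns {sorted(required)}")
    return [
        SiteMethylation(r.chrom, int(r.pos) - 1, r.strand, r.context, int(r.mc_reads), int(r.total_reads))
        for r in df.itertuples()
    ]


def write_methylation_tsv(sites: Iterable[SiteMethylation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tcontext\tmc_reads\ttotal_reads\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos, s.strand)):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.context}\t{s.mc_reads}\t{s.total_reads}\n")
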