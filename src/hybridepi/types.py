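"""Domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)``. Formats that
use other conventions (GFF3, 1-based SNP tables, SAM POS) are converted at the
I/O boundary, never downstream.

Cultivar codes follow the field convention for a hybrid trio: ``H`` the F1
hybrid, ``M`` the maternal parent, ``P`` the paternal parent. Contrasts are
ordered pairs: ``PP`` = M vs P, ``HM`` = H vs M, ``HP`` = H vs P, with the
log2 fold change always first member over second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MARKS = ("H3K4me3", "H3K27me3")
CULTIVARS = ("H", "M", "P")
#: contrast -> (first member, second member) of the fold change
CONTRASTS = {"PP": ("M", "P"), "HM": ("H", "M"), "HP": ("H", "P")}

FEATURE_LABELS = ("promoter-TSS", "exon", "intron", "TTS", "intergenic")

#: half-width of the promoter-TSS (and TTS) window in bp
PROMOTER_HALF_WIDTH = 2000


@dataclass
class GeneModel:
    """A gene with exon/CDS structure and strand-aware TSS/TTS."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start}, {self.end})")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        prev_end = None
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons) if self.exons else self.length

    def promoter_window(self) -> tuple[int, int]:
        """Promoter-TSS window: 2 kb up- and downstream of the TSS, clipped at 0."""
        return (max(0, self.tss - PROMOTER_HALF_WIDTH), self.tss + PROMOTER_HALF_WIDTH + 1)

    def tts_window(self) -> tuple[int, int]:
        return (max(0, self.tts - PROMOTER_HALF_WIDTH), self.tts + PROMOTER_HALF_WIDTH + 1)

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class Peak:
    """A mark-enriched interval called in one cultivar."""

    chrom: str
    start: int
    end: int
    mark: str
    cultivar: str
    fold_enrichment: float
    pvalue: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak start must be < end ({self.start}, {self.end})")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be > 0")


@dataclass(frozen=True)
class SNPRecord:
    """A diagnostic SNP homozygous-different between the two parents."""

    chrom: str
    pos: int  # 0-based
    maternal_base: str
    paternal_base: str

    def __post_init__(self) -> None:
        if self.maternal_base == self.paternal_base:
            raise ValueError(f"SNP at {self.chrom}:{self.pos}: parental bases must differ")


@dataclass
class AlignedRead:
    """Minimal alignment record: everything read partitioning needs."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    cigar: str
    seq: str


@dataclass
class ConsensusRegion:
    """Union of overlapping peaks of one mark across cultivars."""

    region_id: str
    chrom: str
    start: int
    end: int
    mark: str
    contributors: frozenset[str]
    fold_enrichment: float
    gene_id: str | None = None
    feature: str = "intergenic"
    members: list = field(default_factory=list)  # contributing Peak records

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class DHMRecord:
    """Differential histone modification call for one region and contrast."""

    region_id: str
    gene_id: str | None
    contrast: str
    log2fc: float
    pvalue: float
    status: str  # hyper | hypo | ns
    pattern: str | None = None  # inherited | novel (HM/HP contrasts only)


@dataclass
class ASHMRecord:
    """Allele-level histone modification class of one gene in the hybrid."""

    gene_id: str
    mark: str
    ratio: float | None
    informative_reads: int
    klass: str  # BAHM | ASHM-maternal | ASHM-paternal | filtered


@dataclass
class ASERecord:
    """Allele-specific expression call for one gene in the hybrid."""

    gene_id: str
    replicates: list[tuple[int, int]]
    log2_mp: float
    pvalue: float
    bias: str  # maternal | paternal | none


@dataclass
class SiteMethylation:
    chrom: str
    pos: int  # 0-based
    strand: str
    context: str  # CG | CHG | CHH
    mc_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.mc_reads > self.total_reads:
            raise ValueError(f"{self.chrom}:{self.pos}: mc_reads > total_reads")

    @property
    def level(self) -> float:
        return self.mc_reads / self.total_reads if self.total_reads else float("nan")


@dataclass
class GeneMethylation:
    gene_id: str
    cultivar: str
    weighted_level: float | None
    context_levels: dict[str, float | None]
    bin: str  # unmethylated | low | moderate | high | full | no-data


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    context: str
    n_dmcs: int
    mean_diff: float
    direction: int  # +1: higher in first sample, -1: lower


@dataclass
class DEGRecord:
    gene_id: str
    contrast: str
    log2fc: float
    pvalue: float
    fdr: float
    status: str  # up | down | ns
    pattern: str | None = None  # inherited | novel (HM/HP only)
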