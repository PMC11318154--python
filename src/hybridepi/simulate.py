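"""Truth-tracked synthetic data for the full hybrid-trio pipeline.

The generator emulates the data a hybrid/parent epigenome study produces —
peak calls, region read counts, SNP-bearing hybrid alignments, per-cytosine
methylation counts and replicated RNA counts — with planted, recoverable
structure:

* a configurable fraction of analyzable genes with allele-biased hybrid ChIP
  reads (maternal-read probability ``ashm_bias_strength``),
* parent-parent modification differences of configurable log2 effect whose
  propagation to the hybrid is governed by ``inheritance_rate``: the hybrid
  adopts the higher parent's level with that probability, the lower one
  otherwise (plus a small hybrid-specific "novel" class where parents agree),
* expression coupled positively to H3K4me3 and negatively to H3K27me3 and
  DNA methylation, with parent-differential and allele-biased genes,
* differentially methylated regions of stated per-context effect size.

All randomness flows from one :class:`numpy.random.Generator` seeded by the
config, and every writer is deterministic, so a seed fixes the output
byte-for-byte. Base content is synthetic: reads carry real bases only at SNP
columns ('T' elsewhere).
"""

from __future__ import annotations

import bisect
import warnings
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .io import CountTable
from .types import MARKS, AlignedRead, GeneModel, Peak, SiteMethylation, SNPRecord

GENES_PER_CHROM = 500
MIN_SPACER = 5000  # keeps promoter-TSS windows of neighbours disjoint


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 500
    gene_length_mean: int = 2000
    snp_density: float = 0.005  # per bp of CDS
    n_replicates: int = 3
    dispersion: float = 0.1  # negative-binomial overdispersion
    read_length: int = 100
    base_error_rate: float = 0.005  # sequencing error at SNP columns

    # ChIP structure
    target_fraction: dict = field(default_factory=lambda: {"H3K4me3": 0.7, "H3K27me3": 0.3})
    ashm_fraction: float = 0.08
    ashm_bias_strength: float = 0.85
    dhm_pp_fraction: float = 0.2
    dhm_effect_log2fc: float = 2.0
    inheritance_rate: float = 0.7
    novel_dhm_fraction: float = 0.05
    mean_chip_coverage: float = 50.0  # expected region count per replicate
    chip_background_count: float = 2.0
    mean_informative_reads: float = 100.0  # SNP-covering hybrid reads per gene

    # RNA structure
    deg_fraction: float = 0.1
    deg_effect_log2fc: float = 2.0
    ase_fraction: float = 0.08
    ase_bias_strength: float = 0.85
    mean_rna_depth: float = 100.0  # expected count per replicate
    mean_rna_informative_reads: float = 40.0  # per replicate
    nonexpressed_fraction: float = 0.1
    coupling_h3k4me3: float = 0.8  # exponent, positive effect on expression
    coupling_h3k27me3: float = 0.6  # exponent, negative effect
    coupling_methylation: float = 1.0  # log2 penalty per unit methylation

    # methylation structure
    meth_coverage: float = 30.0  # per strand-site
    meth_site_spacing: int = 50
    context_scale: dict = field(default_factory=lambda: {"CG": 1.3, "CHG": 0.8, "CHH": 0.35})
    meth_bin_probs: tuple = (0.70, 0.20, 0.06, 0.035, 0.005)
    dmr_fraction: float = 0.02
    dmr_effect: dict = field(default_factory=lambda: {"CG": 0.5, "CHG": 0.3, "CHH": 0.3})
    dmr_low_level: float = 0.05
    sites_per_dmr: int = 5

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        fracs = {
            "snp_density": self.snp_density, "ashm_fraction": self.ashm_fraction,
            "ashm_bias_strength": self.ashm_bias_strength, "dhm_pp_fraction": self.dhm_pp_fraction,
            "inheritance_rate": self.inheritance_rate, "novel_dhm_fraction": self.novel_dhm_fraction,
            "deg_fraction": self.deg_fraction, "ase_fraction": self.ase_fraction,
            "dmr_fraction": self.dmr_fraction, "base_error_rate": self.base_error_rate,
            "nonexpressed_fraction": self.nonexpressed_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("mean_chip_coverage", "mean_rna_depth", "meth_coverage", "mean_informative_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sites_per_dmr < 3:
            raise ValueError("sites_per_dmr must be >= 3 (a region needs >= 3 sites)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthTable:
    """Planted per-gene truth plus planted DMR intervals."""

    genes: pd.DataFrame  # indexed by gene_id
    dmrs: pd.DataFrame

    def write(self, out_dir: Path) -> None:
        self.genes.sort_index().to_csv(out_dir / "truth_genes.tsv", sep="\t")
        self.dmrs.to_csv(out_dir / "truth_dmrs.tsv", sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial with mean/overdispersion parameterization."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def snps_in_cds_by_gene(
    genes: list[GeneModel], snps: list[SNPRecord]
) -> dict[str, list[SNPRecord]]:
    """CDS-resident diagnostic SNPs per gene (genes are non-overlapping)."""
    out: dict[str, list[SNPRecord]] = {g.gene_id: [] for g in genes}
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    starts = {c: [g.start for g in sorted(gl, key=lambda g: g.start)] for c, gl in by_chrom.items()}
    ordered = {c: sorted(gl, key=lambda g: g.start) for c, gl in by_chrom.items()}
    for s in snps:
        if s.chrom not in starts:
            continue
        i = bisect.bisect_right(starts[s.chrom], s.pos) - 1
        if i < 0:
            continue
        g = ordered[s.chrom][i]
        if s.pos < g.end and any(cs <= s.pos < ce for cs, ce in g.cds):
            out[g.gene_id].append(s)
    return out


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Non-overlapping gene models on synthetic chromosomes plus diagnostic SNPs.

    Returns ``(genes, snps, chrom_lengths)``.
    """
    rng = rng or config.rng()
    genes: list[GeneModel] = []
    snps: list[SNPRecord] = []
    chrom_lengths: dict[str, int] = {}
    bases = np.array(list("ACGT"))
    cursor, chrom_i = 10_000, 1
    for i in range(config.n_genes):
        if i > 0 and i % GENES_PER_CHROM == 0:
            chrom_lengths[f"chr{chrom_i}"] = cursor + 10_000
            chrom_i += 1
            cursor = 10_000
        chrom = f"chr{chrom_i}"
        length = max(600, int(rng.gamma(4.0, config.gene_length_mean / 4.0)))
        start, end = cursor, cursor + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        intron_len = max(60, length // 10) if n_exons > 1 else 0
        exon_len = (length - (n_exons - 1) * intron_len) // n_exons
        exons, pos = [], start
        for j in range(n_exons):
            e_end = end if j == n_exons - 1 else pos + exon_len
            exons.append((pos, e_end))
            pos = e_end + intron_len
        cds_lo, cds_hi = start + 150, end - 150
        cds = [(max(s, cds_lo), min(e, cds_hi)) for s, e in exons if min(e, cds_hi) > max(s, cds_lo)]
        genes.append(GeneModel(f"gene{i:05d}", chrom, strand, start, end, exons=exons, cds=cds))
        for s, e in cds:
            n_snps = int(rng.poisson((e - s) * config.snp_density))
            if n_snps:
                positions = np.sort(rng.choice(np.arange(s, e), size=min(n_snps, e - s), replace=False))
                for p in positions:
                    mb, pb = rng.choice(bases, size=2, replace=False)
                    snps.append(SNPRecord(chrom, int(p), str(mb), str(pb)))
        cursor = end + MIN_SPACER + int(rng.integers(0, 2000))
    chrom_lengths[f"chr{chrom_i}"] = cursor + 10_000
    return genes, snps, chrom_lengths


# ---------------------------------------------------------------------------
# ChIP


def _make_read(
    rng: np.random.Generator,
    read_id: str,
    chrom: str,
    anchor_snp: int,
    gene_snps: list[SNPRecord],
    origin: str,
    config: SimulationConfig,
) -> AlignedRead:
    offset = int(rng.integers(0, config.read_length))
    start = max(0, anchor_snp - offset)
    seq = np.full(config.read_length, "T", dtype="<U1")
    bases = "ACGT"
    for s in gene_snps:
        if start <= s.pos < start + config.read_length:
            base = s.maternal_base if origin == "maternal" else s.paternal_base
            if rng.random() < config.base_error_rate:
                base = bases[int(rng.integers(0, 4))]
            seq[s.pos - start] = base
    return AlignedRead(read_id, chrom, start, f"{config.read_length}M", "".join(seq))


def simulate_chip(
    config: SimulationConfig,
    genes: list[GeneModel],
    snps: list[SNPRecord],
    rng: np.random.Generator,
):
    """Peaks per cultivar x mark, count tables, hybrid SNP reads and truth.

    Returns ``(peaks, counts, hybrid_reads, truth_genes, levels)`` where
    ``levels[mark]`` holds per-gene expected-level multipliers per cultivar,
    reused by the expression coupling.
    """
    snps_by_gene = snps_in_cds_by_gene(genes, snps)
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    truth["n_cds_snps"] = [len(snps_by_gene[gid]) for gid in gene_ids]
    n_snps_arr = truth["n_cds_snps"].to_numpy()

    peaks: dict[tuple[str, str], list[Peak]] = {}
    counts: dict[str, CountTable] = {}
    reads: dict[str, list[AlignedRead]] = {}
    levels: dict[str, pd.DataFrame] = {}

    if config.mean_informative_reads < 10:
        warnings.warn("mean_informative_reads is below the >9-read filter; most genes will be filtered")

    for mark in MARKS:
        is_target = rng.random(n) < config.target_fraction[mark]
        base_mult = rng.lognormal(0.0, 0.4, size=n)
        dhm_dir = np.zeros(n, dtype=int)  # +1: maternal higher
        dhm_mask = is_target & (rng.random(n) < config.dhm_pp_fraction)
        dhm_dir[dhm_mask] = rng.choice([1, -1], size=int(dhm_mask.sum()))
        inherited = rng.random(n) < config.inheritance_rate
        novel_dir = np.zeros(n, dtype=int)
        novel_mask = is_target & (dhm_dir == 0) & (rng.random(n) < config.novel_dhm_fraction)
        novel_dir[novel_mask] = rng.choice([1, -1], size=int(novel_mask.sum()))

        half = config.dhm_effect_log2fc / 2.0
        mult_m = np.where(dhm_dir != 0, 2.0 ** (half * dhm_dir), 1.0)
        mult_p = np.where(dhm_dir != 0, 2.0 ** (-half * dhm_dir), 1.0)
        mult_h = np.where(
            dhm_dir != 0,
            np.where(inherited, np.maximum(mult_m, mult_p), np.minimum(mult_m, mult_p)),
            1.0,
        )
        mult_h = np.where(novel_dir != 0, 2.0 ** (config.dhm_effect_log2fc * novel_dir), mult_h)
        mult = {"M": mult_m, "P": mult_p, "H": mult_h}

        # allele classes among analyzable genes (target with >= 1 CDS SNP)
        analyzable = is_target & (n_snps_arr > 0)
        is_ashm = analyzable & (rng.random(n) < config.ashm_fraction)
        ashm_side = rng.choice(["maternal", "paternal"], size=n)
        klass = [
            "NA" if not analyzable[i] else (f"ASHM-{ashm_side[i]}" if is_ashm[i] else "BAHM")
            for i in range(n)
        ]

        truth[f"target_{mark}"] = is_target
        truth[f"dhm_pp_dir_{mark}"] = dhm_dir
        truth[f"dhm_inherited_{mark}"] = np.where(dhm_dir != 0, inherited, False)
        truth[f"novel_dhm_dir_{mark}"] = novel_dir
        truth[f"ashm_class_{mark}"] = klass
        levels[mark] = pd.DataFrame(
            {c: mult[c] * base_mult * np.where(is_target, 1.0, 0.0) for c in ("M", "P", "H")},
            index=truth.index,
        )

        # peaks: promoter-anchored for most target genes, gene-body for some
        body_peak = rng.random(n) < 0.15
        for cultivar in ("M", "P", "H"):
            plist = []
            for i, g in enumerate(genes):
                if not is_target[i]:
                    continue
                if body_peak[i]:
                    mid = (g.start + g.end) // 2
                    s, e = max(0, mid - 600), mid + 600
                else:
                    s, e = max(0, g.tss - 800), g.tss + 800
                fe = 5.0 * base_mult[i] * float(mult[cultivar][i])
                plist.append(Peak(g.chrom, s, e, mark, cultivar, max(fe, 0.01), 1e-6))
            peaks[(cultivar, mark)] = plist

        # counts: NB per replicate around coverage x multiplier
        cols, data = [], []
        for cultivar in ("M", "P", "H"):
            expected = np.where(
                is_target,
                config.mean_chip_coverage * base_mult * mult[cultivar],
                config.chip_background_count,
            )
            for rep in range(1, config.n_replicates + 1):
                cols.append(f"{cultivar}_rep{rep}")
                data.append(_nb_draw(rng, expected, config.dispersion))
        count_df = pd.DataFrame(np.column_stack(data), index=truth.index, columns=cols)
        lib = int(config.n_genes * config.mean_chip_coverage * 10)
        counts[mark] = CountTable(count_df, pd.Series(lib, index=cols))

        # hybrid SNP-covering reads
        mark_reads: list[AlignedRead] = []
        n_covered = 0
        for i, g in enumerate(genes):
            if not analyzable[i]:
                continue
            gsnps = snps_by_gene[g.gene_id]
            lam = config.mean_informative_reads * float(mult_h[i]) * base_mult[i]
            n_reads = int(_nb_draw(rng, [lam], config.dispersion)[0])
            p_mat = {
                "BAHM": 0.5,
                "ASHM-maternal": config.ashm_bias_strength,
                "ASHM-paternal": 1.0 - config.ashm_bias_strength,
            }[klass[i]]
            for r in range(n_reads):
                anchor = gsnps[int(rng.integers(0, len(gsnps)))]
                origin = "maternal" if rng.random() < p_mat else "paternal"
                mark_reads.append(
                    _make_read(rng, f"{mark}:{g.gene_id}:{r}", g.chrom, anchor.pos, gsnps, origin, config)
                )
            n_covered += n_reads > 0
        if analyzable.any() and n_covered == 0:
            warnings.warn(f"{mark}: ChIP coverage too low to yield any SNP-covering read")
        reads[mark] = mark_reads

    return peaks, counts, reads, truth, levels


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation(
    config: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
):
    """Per-site methylation per cultivar with planted parent-parent DMRs.

    Returns ``(sites_by_cultivar, gene_base_level, truth_dmrs)``. Planted
    DMRs differ between the parents (the hybrid keeps the low level) over
    ``sites_per_dmr`` consecutive same-context cytosines.
    """
    from .methylation import DMC_DIFF_THRESHOLDS

    for ctx, eff in config.dmr_effect.items():
        if eff < DMC_DIFF_THRESHOLDS[ctx]:
            warnings.warn(
                f"dmr_effect for {ctx} ({eff}) is below the calling threshold; planted truth unrecoverable"
            )
    bin_lows = np.array([0.0, 0.12, 0.42, 0.62, 0.92])
    bin_highs = np.array([0.08, 0.38, 0.58, 0.88, 0.98])
    which = rng.choice(len(bin_lows), size=len(genes), p=np.asarray(config.meth_bin_probs))
    gene_base = rng.uniform(bin_lows[which], bin_highs[which])

    is_dmr = rng.random(len(genes)) < config.dmr_fraction
    dmr_ctx_all = rng.choice(["CG", "CHG", "CHH"], size=len(genes), p=[0.6, 0.2, 0.2])
    dmr_high_in_m = rng.random(len(genes)) < 0.5

    sites: dict[str, list[SiteMethylation]] = {"M": [], "P": [], "H": []}
    dmr_rows = []
    contexts = np.array(["CG", "CHG", "CHH"])
    for i, g in enumerate(genes):
        positions = np.arange(g.start + 10, g.end - 2, config.meth_site_spacing)
        if positions.size == 0:
            continue
        ctx = contexts[rng.choice(3, size=positions.size, p=[0.4, 0.3, 0.3])]
        in_dmr = np.zeros(positions.size, dtype=bool)
        if is_dmr[i] and positions.size >= config.sites_per_dmr:
            # a DMR is a run of consecutive cytosines of one context, so the
            # inter-site gap stays within the caller's chaining distance
            ctx_i = str(dmr_ctx_all[i])
            j0 = int(rng.integers(0, positions.size - config.sites_per_dmr + 1))
            sel = slice(j0, j0 + config.sites_per_dmr)
            ctx[sel] = ctx_i
            in_dmr[sel] = True
            dmr_rows.append(
                {
                    "chrom": g.chrom,
                    "start": int(positions[j0]),
                    "end": int(positions[j0 + config.sites_per_dmr - 1]) + 1,
                    "context": ctx_i,
                    "gene_id": g.gene_id,
                    "high_cultivar": "M" if dmr_high_in_m[i] else "P",
                    "effect": config.dmr_effect[ctx_i],
                    "n_sites": int(config.sites_per_dmr),
                }
            )
        base_level = {
            c: float(np.clip(gene_base[i] * config.context_scale[c], 0.0, 1.0))
            for c in ("CG", "CHG", "CHH")
        }
        lvl = np.array([base_level[c] for c in ctx])
        # expand CG sites to both strands (records at p and p+1)
        rec_pos, rec_strand, rec_ctx, rec_lvl_idx = [], [], [], []
        for j, (p, c) in enumerate(zip(positions, ctx)):
            rec_pos.append(int(p)); rec_strand.append("+"); rec_ctx.append(str(c)); rec_lvl_idx.append(j)
            if c == "CG":
                rec_pos.append(int(p) + 1); rec_strand.append("-"); rec_ctx.append("CG"); rec_lvl_idx.append(j)
        rec_lvl_idx = np.asarray(rec_lvl_idx)
        for cultivar in ("M", "P", "H"):
            lvl_c = lvl.copy()
            if is_dmr[i] and in_dmr.any():
                high = (cultivar == "M") == bool(dmr_high_in_m[i])
                dmr_level = config.dmr_low_level + (
                    config.dmr_effect[str(dmr_ctx_all[i])] if high and cultivar != "H" else 0.0
                )
                lvl_c[in_dmr] = dmr_level
            cov = np.maximum(1, rng.poisson(config.meth_coverage, size=len(rec_pos)))
            mc = rng.binomial(cov, lvl_c[rec_lvl_idx])
            for k in range(len(rec_pos)):
                sites[cultivar].append(
                    SiteMethylation(g.chrom, rec_pos[k], rec_strand[k], rec_ctx[k], int(mc[k]), int(cov[k]))
                )
    truth_dmrs = pd.DataFrame(
        dmr_rows,
        columns=["chrom", "start", "end", "context", "gene_id", "high_cultivar", "effect", "n_sites"],
    )
    return sites, pd.Series(gene_base, index=[g.gene_id for g in genes]), truth_dmrs


# ---------------------------------------------------------------------------
# RNA


def simulate_rna(
    config: SimulationConfig,
    genes: list[GeneModel],
    snps: list[SNPRecord],
    truth: pd.DataFrame,
    chip_levels: dict[str, pd.DataFrame],
    gene_meth: pd.Series,
    rng: np.random.Generator,
):
    """Replicated RNA counts, hybrid allele reads per replicate, truth update."""
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (cross-replicate consistency undefined)")
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    snps_by_gene = snps_in_cds_by_gene(genes, snps)

    expressed = rng.random(n) >= config.nonexpressed_fraction
    base_expr = np.where(expressed, rng.lognormal(np.log(config.mean_rna_depth), 1.0, size=n), 0.0)

    deg_dir = np.zeros(n, dtype=int)  # +1: maternal higher
    deg_mask = expressed & (rng.random(n) < config.deg_fraction)
    deg_dir[deg_mask] = rng.choice([1, -1], size=int(deg_mask.sum()))
    deg_inherited = rng.random(n) < config.inheritance_rate

    half = config.deg_effect_log2fc / 2.0
    dmult = {
        "M": np.where(deg_dir != 0, 2.0 ** (half * deg_dir), 1.0),
        "P": np.where(deg_dir != 0, 2.0 ** (-half * deg_dir), 1.0),
    }
    high = np.maximum(dmult["M"], dmult["P"])
    low = np.minimum(dmult["M"], dmult["P"])
    dmult["H"] = np.where(deg_dir != 0, np.where(deg_inherited, high, low), 1.0)

    meth = gene_meth.reindex(gene_ids).to_numpy()
    coupling = {}
    for cultivar in ("M", "P", "H"):
        k4 = np.maximum(chip_levels["H3K4me3"][cultivar].to_numpy(), 0.3)
        k27 = np.maximum(chip_levels["H3K27me3"][cultivar].to_numpy(), 0.3)
        coupling[cultivar] = (
            k4**config.coupling_h3k4me3
            * k27 ** (-config.coupling_h3k27me3)
            * 2.0 ** (-config.coupling_methylation * meth)
        )

    cols, data = [], []
    for cultivar in ("M", "P", "H"):
        expected = base_expr * dmult[cultivar] * coupling[cultivar]
        for rep in range(1, config.n_replicates + 1):
            cols.append(f"{cultivar}_rep{rep}")
            data.append(_nb_draw(rng, expected, config.dispersion))
    count_df = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    lib = int(config.n_genes * config.mean_rna_depth * 10)
    counts = CountTable(count_df, pd.Series(lib, index=cols))

    has_snp = np.array([len(snps_by_gene[gid]) > 0 for gid in gene_ids])
    is_ase = expressed & has_snp & (rng.random(n) < config.ase_fraction)
    ase_side = rng.choice(["maternal", "paternal"], size=n)
    ase_class = [
        "NA" if not (expressed[i] and has_snp[i]) else (f"ASE-{ase_side[i]}" if is_ase[i] else "biallelic")
        for i in range(n)
    ]

    reads_by_rep: dict[int, list[AlignedRead]] = {r: [] for r in range(1, config.n_replicates + 1)}
    for i, g in enumerate(genes):
        if not (expressed[i] and has_snp[i]):
            continue
        gsnps = snps_by_gene[g.gene_id]
        scale = float(np.clip(base_expr[i] * dmult["H"][i] / config.mean_rna_depth, 0.2, 5.0))
        p_mat = {
            "biallelic": 0.5,
            "ASE-maternal": config.ase_bias_strength,
            "ASE-paternal": 1.0 - config.ase_bias_strength,
        }[ase_class[i]]
        for rep in range(1, config.n_replicates + 1):
            n_reads = int(rng.poisson(config.mean_rna_informative_reads * scale))
            for r in range(n_reads):
                anchor = gsnps[int(rng.integers(0, len(gsnps)))]
                origin = "maternal" if rng.random() < p_mat else "paternal"
                reads_by_rep[rep].append(
                    _make_read(rng, f"rna:rep{rep}:{g.gene_id}:{r}", g.chrom, anchor.pos, gsnps, origin, config)
                )

    truth = truth.copy()
    truth["expressed"] = expressed
    truth["deg_pp_dir"] = deg_dir
    truth["deg_inherited"] = np.where(deg_dir != 0, deg_inherited, False)
    truth["ase_class"] = ase_class
    truth["meth_base_level"] = meth
    return counts, reads_by_rep, truth


# ---------------------------------------------------------------------------
# bundle


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> TruthTable:
    """Run the full generator and write every pipeline input under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    genes, snps, chrom_lengths = simulate_genome(config, rng)
    peaks, chip_counts, chip_reads, truth, levels = simulate_chip(config, genes, snps, rng)
    meth_sites, gene_meth, truth_dmrs = simulate_methylation(config, genes, rng)
    rna_counts, rna_reads, truth = simulate_rna(config, genes, snps, truth, levels, gene_meth, rng)

    hio.write_gene_models_gff3(genes, out_dir / "genes.gff3")
    hio.write_snps_tsv(snps, out_dir / "snps.tsv")
    for (cultivar, mark), plist in peaks.items():
        hio.write_peaks_bed(plist, out_dir / f"peaks_{cultivar}_{mark}.bed")
    for mark in MARKS:
        hio.write_count_table(chip_counts[mark], out_dir / f"chip_counts_{mark}.tsv")
        hio.write_sam(chip_reads[mark], out_dir / f"chip_hybrid_{mark}.sam", chrom_lengths)
    for cultivar, site_list in meth_sites.items():
        hio.write_methylation_tsv(site_list, out_dir / f"methylation_{cultivar}.tsv")
    hio.write_count_table(rna_counts, out_dir / "rna_counts.tsv")
    for rep, rreads in rna_reads.items():
        hio.write_sam(rreads, out_dir / f"rna_hybrid_rep{rep}.sam", chrom_lengths)

    table = TruthTable(genes=truth, dmrs=truth_dmrs)
    table.write(out_dir)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return table
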