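"""End-to-end pipeline: DHM -> allele-level (ASHM/ASE) -> methylation ->
integration, from a directory of standard-format inputs to per-stage TSV/BED
outputs and one machine-readable JSON summary.

Expected input layout (the synthetic-data generator writes exactly this):

    genes.gff3                    gene models
    snps.tsv                      diagnostic parental SNPs
    peaks_{C}_{mark}.bed          peak calls, C in {M, P, H}
    chip_counts_{mark}.tsv        region counts with library_size row
    chip_hybrid_{mark}.sam        hybrid ChIP alignments
    rna_counts.tsv                replicated RNA counts
    rna_hybrid_rep{i}.sam         hybrid RNA alignments per replicate
    methylation_{C}.tsv           per-cytosine counts per cultivar

Any stage failure aborts the run with the stage name; outputs already
written for the failed run are removed.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import allele, dhm, expression, integrate, methylation
from . import io as hio
from .types import CONTRASTS, CULTIVARS, MARKS, GeneModel

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    genes: list[GeneModel]
    regions: dict = dc_field(default_factory=dict)  # mark -> [ConsensusRegion]
    dhm_records: dict = dc_field(default_factory=dict)  # (mark, contrast) -> [DHMRecord]
    target_genes: dict = dc_field(default_factory=dict)  # (mark, cultivar) -> set
    ashm: dict = dc_field(default_factory=dict)  # mark -> [ASHMRecord]
    allele_counts: dict = dc_field(default_factory=dict)  # mark -> [AlleleCount]
    ase: list = dc_field(default_factory=list)  # [ASERecord]
    gene_meth: dict = dc_field(default_factory=dict)  # cultivar -> {gene: GeneMethylation}
    dmrs: dict = dc_field(default_factory=dict)  # (contrast, context) -> [DMR]
    degs: dict = dc_field(default_factory=dict)  # contrast -> [DEGRecord]
    rpkms: pd.DataFrame | None = None
    profiles: dict = dc_field(default_factory=dict)  # contrast -> [EpiVariationProfile]
    summary: dict = dc_field(default_factory=dict)


def _direction_by_gene(records) -> dict[str, int]:
    """Gene-level differential direction from region/gene records.

    Multiple regions per gene: the most significant call wins.
    """
    best: dict[str, tuple[float, int]] = {}
    for r in records:
        if r.status == "ns" or r.gene_id is None:
            continue
        d = 1 if r.status in ("hyper", "up") else -1
        if r.gene_id not in best or r.pvalue < best[r.gene_id][0]:
            best[r.gene_id] = (r.pvalue, d)
    return {g: d for g, (_, d) in best.items()}


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    count_region: str = "gene-body",
    expressed_min_rpkm: float = 0.0,
) -> PipelineResult:
    """Execute every stage in order and write the report bundle.

    ``expressed_min_rpkm``: genes with RPKM strictly above this count as
    expressed (default: RPKM > 0).
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    result: PipelineResult

    def _write(path: Path):
        written.append(path)
        return path

    try:
        stage = "load"
        genes = hio.read_gene_models(input_dir / "genes.gff3")
        result = PipelineResult(genes=genes)
        findex = dhm.FeatureIndex(genes)

        stage = "dhm"
        dhm_rows = []
        for mark in MARKS:
            peaks = []
            for cultivar in CULTIVARS:
                peaks.extend(
                    hio.read_peaks_bed(input_dir / f"peaks_{cultivar}_{mark}.bed", mark, cultivar)
                )
            regions = [dhm.annotate_region(r, findex) for r in dhm.build_consensus(peaks, mark)]
            result.regions[mark] = regions
            for cultivar in CULTIVARS:
                result.target_genes[(mark, cultivar)] = {
                    r.gene_id for r in regions if r.gene_id and cultivar in r.contributors
                }
            counts = hio.read_count_table(input_dir / f"chip_counts_{mark}.tsv")
            for contrast in CONTRASTS:
                result.dhm_records[(mark, contrast)] = dhm.call_dhm(regions, counts, contrast)
            exclude = dhm.conflicting_regions(
                result.dhm_records[(mark, "HM")], result.dhm_records[(mark, "HP")]
            )
            origin_summaries = {}
            for contrast in ("HM", "HP"):
                result.dhm_records[(mark, contrast)], origin_summaries[contrast] = dhm.attribute_origin(
                    result.dhm_records[(mark, contrast)],
                    result.dhm_records[(mark, "PP")],
                    exclude=exclude,
                )
            result.summary.setdefault("dhm", {})[mark] = {
                "n_regions": len(regions),
                "n_dhm": {
                    c: sum(1 for r in result.dhm_records[(mark, c)] if r.status != "ns")
                    for c in CONTRASTS
                },
                "origin": origin_summaries,
            }
            region_by_id = {x.region_id: x for x in regions}
            for contrast in CONTRASTS:
                for r in result.dhm_records[(mark, contrast)]:
                    region = region_by_id[r.region_id]
                    dhm_rows.append(
                        {
                            "region_id": r.region_id, "gene_id": r.gene_id or "",
                            "feature": region.feature, "mark": mark, "contrast": contrast,
                            "log2fc": f"{r.log2fc:.6g}", "pvalue": f"{r.pvalue:.6g}",
                            "status": r.status, "pattern": r.pattern or "",
                        }
                    )
        pd.DataFrame(dhm_rows).to_csv(_write(out_dir / "dhm.tsv"), sep="\t", index=False)

        stage = "ashm"
        snps = hio.read_snps(input_dir / "snps.tsv")
        ashm_rows = []
        for mark in MARKS:
            reads = hio.iter_sam(input_dir / f"chip_hybrid_{mark}.sam")
            counts = allele.partition_reads(reads, snps, genes, count_region=count_region, assay=mark)
            result.allele_counts[mark] = counts
            result.ashm[mark] = [allele.classify_ashm(c, mark) for c in counts]
            class_counts = pd.Series([r.klass for r in result.ashm[mark]]).value_counts().to_dict()
            class_counts.pop("filtered", None)
            result.summary.setdefault("ashm", {})[mark] = allele.summarize_allele_classes(class_counts)
            for r in result.ashm[mark]:
                ashm_rows.append(
                    {
                        "gene_id": r.gene_id, "mark": mark,
                        "ratio": "" if r.ratio is None else f"{r.ratio:.6g}",
                        "informative_reads": r.informative_reads, "class": r.klass,
                    }
                )
            # association with hybrid-parent DHMs and correlation with parental differences
            dhm_hp_genes = {
                r.gene_id
                for c in ("HM", "HP")
                for r in result.dhm_records[(mark, c)]
                if r.status != "ns" and r.gene_id
            }
            analyzable = {r.gene_id for r in result.ashm[mark] if r.klass != "filtered"}
            if analyzable and dhm_hp_genes & analyzable:
                assoc = allele.ashm_dhm_association(
                    result.ashm[mark], dhm_hp_genes & analyzable, analyzable
                )
                result.summary["ashm"][mark]["dhm_association"] = {
                    k: v for k, v in assoc.items() if k != "table"
                }
            pp_fc = {
                r.gene_id: r.log2fc
                for r in result.dhm_records[(mark, "PP")]
                if r.gene_id is not None
            }
            ratios = {r.gene_id: r.ratio for r in result.ashm[mark] if r.klass != "filtered"}
            shared = set(pp_fc) & set(ratios)
            if len(shared) >= 3:
                try:
                    rho = allele.dhm_ashm_correlation(pp_fc, ratios)
                    result.summary["ashm"][mark]["dhm_pp_allele_ratio_spearman"] = rho
                except ValueError:
                    pass
        pd.DataFrame(ashm_rows).to_csv(_write(out_dir / "ashm.tsv"), sep="\t", index=False)

        stage = "ase"
        rep_paths = sorted(
            input_dir.glob("rna_hybrid_rep*.sam"),
            key=lambda p: int(re.search(r"rep(\d+)", p.name).group(1)),
        )
        if not rep_paths:
            raise FileNotFoundError("no rna_hybrid_rep*.sam files found")
        per_rep = []
        for rep, path in enumerate(rep_paths, 1):
            counts = allele.partition_reads(
                hio.iter_sam(path), snps, genes, count_region=count_region, assay="RNA", replicate=rep
            )
            per_rep.append({c.gene_id: c for c in counts})
        ase_records = []
        for g in genes:
            reps = [
                (per_rep[r][g.gene_id].maternal_reads, per_rep[r][g.gene_id].paternal_reads)
                for r in range(len(per_rep))
            ]
            if any(m + p == 0 for m, p in reps):
                continue
            rec = allele.call_ase(reps, g.gene_id)
            if rec is not None:
                ase_records.append(rec)
        result.ase = ase_records
        with open(_write(out_dir / "ase.tsv"), "w") as fh:
            fh.write("gene_id\tlog2_mp\tpvalue\tbias\n")
            for r in ase_records:
                fh.write(f"{r.gene_id}\t{r.log2_mp:.6g}\t{r.pvalue:.6g}\t{r.bias}\n")
        result.summary["ase"] = {
            "n_tested": len(ase_records),
            "n_aseg": sum(1 for r in ase_records if r.bias != "none"),
        }
        for mark in MARKS:
            result.summary["ashm"][mark]["ase_concordance"] = allele.ashm_ase_concordance(
                result.ashm[mark], ase_records
            )

        stage = "methylation"
        sites = {}
        for cultivar in CULTIVARS:
            raw = hio.read_methylation_tsv(input_dir / f"methylation_{cultivar}.tsv")
            sites[cultivar] = methylation.combine_cg_strands(raw)
        meth_rows = []
        for cultivar in CULTIVARS:
            by_gene = {}
            # bucket sites by gene with a per-chromosome bisect over sorted positions
            by_chrom: dict[str, list] = {}
            for s in sites[cultivar]:
                by_chrom.setdefault(s.chrom, []).append(s)
            pos_arrays = {c: [s.pos for s in sl] for c, sl in by_chrom.items()}
            import bisect as _bisect

            for g in genes:
                sl = by_chrom.get(g.chrom, [])
                pa = pos_arrays.get(g.chrom, [])
                lo = _bisect.bisect_left(pa, g.start)
                hi = _bisect.bisect_left(pa, g.end)
                body = sl[lo:hi]
                gm = methylation.gene_weighted_level(g, body, cultivar=cultivar)
                by_gene[g.gene_id] = gm
                meth_rows.append(
                    {
                        "gene_id": g.gene_id, "cultivar": cultivar,
                        "weighted_level": "" if gm.weighted_level is None else f"{gm.weighted_level:.6g}",
                        "bin": gm.bin,
                    }
                )
            result.gene_meth[cultivar] = by_gene
        pd.DataFrame(meth_rows).to_csv(_write(out_dir / "gene_methylation.tsv"), sep="\t", index=False)
        for contrast, (a, b) in CONTRASTS.items():
            for context in ("CG", "CHG", "CHH"):
                dmcs = methylation.call_dmcs(sites[a], sites[b], context)
                result.dmrs[(contrast, context)] = methylation.call_dmrs(dmcs)
            all_dmrs = [d for ctx in ("CG", "CHG", "CHH") for d in result.dmrs[(contrast, ctx)]]
            methylation.write_dmr_bed(all_dmrs, _write(out_dir / f"dmr_{contrast}.bed"))
        result.summary["methylation"] = {
            "n_dmrs": {
                f"{c}:{ctx}": len(result.dmrs[(c, ctx)])
                for c in CONTRASTS
                for ctx in ("CG", "CHG", "CHH")
            }
        }

        stage = "integration"
        rna_counts = hio.read_count_table(input_dir / "rna_counts.tsv")
        result.rpkms = expression.rpkm_table(rna_counts, genes)
        for contrast in CONTRASTS:
            result.degs[contrast] = expression.call_degs(rna_counts, contrast)
        deg_rows = []
        for contrast in CONTRASTS:
            for r in result.degs[contrast]:
                deg_rows.append(
                    {
                        "gene_id": r.gene_id, "contrast": contrast,
                        "log2fc": f"{r.log2fc:.6g}", "pvalue": f"{r.pvalue:.6g}",
                        "fdr": f"{r.fdr:.6g}", "status": r.status, "pattern": r.pattern or "",
                    }
                )
        result.summary["expression"] = {
            "n_deg": {c: sum(1 for r in result.degs[c] if r.status != "ns") for c in CONTRASTS}
        }

        # Table-1-style cross-tab: methylation bins of histone target genes
        crosstab = {}
        for mark in MARKS:
            for cultivar in CULTIVARS:
                targets = result.target_genes[(mark, cultivar)]
                if not targets:
                    continue
                bins = {g: result.gene_meth[cultivar][g].bin for g in targets if g in result.gene_meth[cultivar]}
                counts_ = methylation.methylation_bin_table(bins, set(bins))
                crosstab[f"{mark}:{cultivar}"] = integrate.methylation_histone_crosstab(counts_)
        result.summary["methylation_histone_crosstab"] = crosstab

        # four-set mutual occupancy per cultivar
        occupancy = {}
        for cultivar in CULTIVARS:
            sub = result.rpkms[result.rpkms["cultivar"] == cultivar]
            expressed = set(sub.loc[sub["rpkm"] > expressed_min_rpkm, "gene_id"])
            methylated = {
                gid for gid, gm in result.gene_meth[cultivar].items()
                if gm.bin not in ("unmethylated", "no-data")
            }
            part = integrate.four_set_overlap(
                expressed,
                result.target_genes[("H3K4me3", cultivar)],
                result.target_genes[("H3K27me3", cultivar)],
                methylated,
            )
            occupancy[cultivar] = {"+".join(k): v for k, v in sorted(part.items())}
        result.summary["four_set_overlap"] = occupancy

        # DEG epigenetic-variation profiles and inheritance
        epi_summary = {}
        for contrast in CONTRASTS:
            a, b = CONTRASTS[contrast]
            dhm_dir = {
                mark: _direction_by_gene(result.dhm_records[(mark, contrast)]) for mark in MARKS
            }
            dmr_genes = methylation.genes_overlapping_dmrs(
                genes, [d for ctx in ("CG", "CHG", "CHH") for d in result.dmrs[(contrast, ctx)]]
            )
            meth_dir = integrate.methylation_variation(
                result.gene_meth[a], result.gene_meth[b], dmr_genes
            )
            profiles, summ = integrate.classify_deg_epivariation(
                result.degs[contrast], dhm_dir, meth_dir
            )
            result.profiles[contrast] = profiles
            epi_summary[contrast] = {
                "n_degs": summ["n_degs"],
                "n_no_epivariation": summ["n_no_epivariation"],
                "fraction_with_epivariation": summ["fraction_with_epivariation"],
                "category_counts": {
                    f"{k[0]}|{'+'.join(k[1]) or 'none'}|{','.join(f'{l}:{int(c)}' for l, c in k[2])}": v
                    for k, v in sorted(summ["category_counts"].items(), key=lambda kv: str(kv[0]))
                },
            }
        result.summary["deg_epivariation"] = epi_summary
        inh_summary = {}
        for contrast in ("HM", "HP"):
            category = {p.gene_id: p.combination for p in result.profiles[contrast]}
            result.degs[contrast], summ = integrate.deg_inheritance(
                result.degs[contrast], result.degs["PP"], category=category
            )
            inh_summary[contrast] = summ
        result.summary["deg_inheritance"] = inh_summary
        # refresh pattern column now that inheritance is attributed
        deg_rows = []
        for contrast in CONTRASTS:
            for r in result.degs[contrast]:
                deg_rows.append(
                    {
                        "gene_id": r.gene_id, "contrast": contrast,
                        "log2fc": f"{r.log2fc:.6g}", "pvalue": f"{r.pvalue:.6g}",
                        "fdr": f"{r.fdr:.6g}", "status": r.status, "pattern": r.pattern or "",
                    }
                )
        pd.DataFrame(deg_rows).to_csv(_write(out_dir / "deg.tsv"), sep="\t", index=False)

        stage = "report"
        with open(_write(out_dir / "summary.json"), "w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
    except Exception as exc:  # noqa: BLE001 - abort names the stage, partial outputs removed
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return result
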