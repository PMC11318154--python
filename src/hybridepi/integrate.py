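"""Cross-layer integration: methylation-by-histone cross-tabs, classification
of differentially expressed genes (DEGs) by epigenetic variation, and DEG
inheritance from the parental contrast.

The epigenetic-variation profile of a DEG records, for the same contrast,
which of three layers vary — H3K4me3, H3K27me3, DNA methylation — the
direction of each, and whether that direction is *consistent* with the
expression change: the activating H3K4me3 is consistent when it moves with
expression, the repressive H3K27me3 and DNA methylation when they move
against it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .stats import percent
from .types import DEGRecord, GeneMethylation

LAYERS = ("H3K4me3", "H3K27me3", "methylation")
#: activating layers move with expression; the rest against it
_ACTIVATING = {"H3K4me3"}

METH_GENE_DIFF_MIN = 0.1


@dataclass
class EpiVariationProfile:
    gene_id: str
    contrast: str
    deg_direction: str  # up | down
    layer_direction: dict[str, int] = field(default_factory=dict)  # +1 higher in first member
    layer_consistent: dict[str, bool] = field(default_factory=dict)
    inherited_from_pp: bool | None = None

    @property
    def n_layers_varying(self) -> int:
        return len(self.layer_direction)

    @property
    def combination(self) -> tuple[str, ...]:
        return tuple(l for l in LAYERS if l in self.layer_direction)

    @property
    def consistency_pattern(self) -> tuple[tuple[str, bool], ...]:
        return tuple((l, self.layer_consistent[l]) for l in self.combination)


def methylation_histone_crosstab(bin_counts: Mapping[str, int]) -> dict[str, dict]:
    """Counts and printed-precision percentages per methylation bin.

    ``bin_counts`` maps the five bin labels of one cultivar x mark column to
    gene counts; percentages are rendered to two decimals, half away from
    zero, as in published tables.
    """
    total = sum(bin_counts.values())
    if total == 0:
        raise ValueError("empty target set: no genes to cross-tabulate")
    return {
        b: {"count": n, "percent": percent(n, total, 2)} for b, n in bin_counts.items()
    }


def methylation_variation(
    meth_a: Mapping[str, GeneMethylation],
    meth_b: Mapping[str, GeneMethylation],
    dmr_genes: set[str] | None = None,
    min_diff: float = METH_GENE_DIFF_MIN,
) -> dict[str, int]:
    """Per-gene methylation-variation direction between two cultivars.

    A gene varies when its weighted-level difference reaches ``min_diff`` or
    it overlaps a DMR between the two samples; direction is the sign of the
    gene-level difference (first minus second).
    """
    dmr_genes = dmr_genes or set()
    out: dict[str, int] = {}
    for gid in set(meth_a) | set(meth_b) | dmr_genes:
        ga, gb = meth_a.get(gid), meth_b.get(gid)
        if ga is None or gb is None or ga.weighted_level is None or gb.weighted_level is None:
            continue
        diff = ga.weighted_level - gb.weighted_level
        if abs(diff) >= min_diff or gid in dmr_genes:
            out[gid] = 1 if diff >= 0 else -1
    return out


def classify_deg_epivariation(
    degs: Sequence[DEGRecord],
    dhm_direction: Mapping[str, Mapping[str, int]],
    meth_direction: Mapping[str, int],
) -> tuple[list[EpiVariationProfile], dict]:
    """Profile every significant DEG by which epigenetic layers vary with it.

    ``dhm_direction`` maps mark -> {gene_id: +1/-1} for genes with a
    significant DHM in the same contrast (+1 = higher in the first contrast
    member); ``meth_direction`` likewise for DNA methylation. A DEG gene
    absent from a layer simply has that layer not varying.
    """
    profiles = []
    counts: dict = defaultdict(int)
    for deg in degs:
        if deg.status == "ns":
            continue
        expr_dir = 1 if deg.status == "up" else -1
        prof = EpiVariationProfile(deg.gene_id, deg.contrast, deg.status)
        for layer in LAYERS:
            source = meth_direction if layer == "methylation" else dhm_direction.get(layer, {})
            d = source.get(deg.gene_id)
            if d is None:
                continue
            prof.layer_direction[layer] = d
            same = d == expr_dir
            prof.layer_consistent[layer] = same if layer in _ACTIVATING else not same
        profiles.append(prof)
        counts[(prof.n_layers_varying, prof.combination, prof.consistency_pattern)] += 1
    n_deg = len(profiles)
    n_none = sum(1 for p in profiles if p.n_layers_varying == 0)
    summary = {
        "n_degs": n_deg,
        "n_no_epivariation": n_none,
        "fraction_with_epivariation": (n_deg - n_none) / n_deg if n_deg else float("nan"),
        "category_counts": dict(counts),
    }
    return profiles, summary


def deg_inherited_direction(hx_contrast: str, hx_status: str) -> str:
    """Parental DEG status implying inheritance of a hybrid-parent DEG."""
    if hx_contrast == "HM":
        return "down" if hx_status == "up" else "up"
    if hx_contrast == "HP":
        return hx_status
    raise ValueError(f"inheritance is defined for HM/HP contrasts, not {hx_contrast!r}")


def deg_inheritance(
    deg_hx: Sequence[DEGRecord],
    deg_pp: Sequence[DEGRecord],
    category: Mapping[str, object] | None = None,
) -> tuple[list[DEGRecord], dict]:
    """Flag each significant hybrid-parent DEG as inherited from the parental
    contrast (same mapping as DHM origin attribution) and summarize fractions,
    optionally stratified by a per-gene category (e.g. epigenetic profile)."""
    pp_status = {r.gene_id: r.status for r in deg_pp if r.status != "ns"}
    n_inh = n_tot = 0
    strat: dict = defaultdict(lambda: [0, 0])
    out = []
    for rec in deg_hx:
        if rec.status == "ns":
            rec.pattern = None
            out.append(rec)
            continue
        want = deg_inherited_direction(rec.contrast, rec.status)
        rec.pattern = "inherited" if pp_status.get(rec.gene_id) == want else "novel"
        out.append(rec)
        n_tot += 1
        inh = rec.pattern == "inherited"
        n_inh += inh
        if category is not None and rec.gene_id in category:
            cell = strat[category[rec.gene_id]]
            cell[0] += inh
            cell[1] += 1
    summary = {
        "n_deg": n_tot,
        "n_inherited": n_inh,
        "fraction_inherited": n_inh / n_tot if n_tot else 0.0,
        "by_category": {
            str(k): {"inherited": v[0], "total": v[1], "fraction": v[0] / v[1]}
            for k, v in sorted(strat.items(), key=lambda kv: str(kv[0]))
        },
    }
    return out, summary


def four_set_overlap(
    expressed: set[str],
    h3k4me3_targets: set[str],
    h3k27me3_targets: set[str],
    methylated: set[str],
) -> dict[tuple[str, ...], int]:
    """Counts for all intersection regions of the four gene sets."""
    from .dhm import target_set_overlap

    return target_set_overlap(
        {
            "expressed": expressed,
            "H3K4me3": h3k4me3_targets,
            "H3K27me3": h3k27me3_targets,
            "methylated": methylated,
        }
    )
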