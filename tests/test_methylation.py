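from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridepi.methylation import (
    DMC,
    assign_methylation_bin,
    call_dmcs,
    call_dmrs,
    call_methylated_sites,
    combine_cg_strands,
    gene_weighted_level,
    site_binomial_test,
)
from hybridepi.types import GeneModel, SiteMethylation
from oracles import binomial_upper_tail, fisher_two_sided


def _site(pos, strand="+", context="CG", mc=5, total=10, chrom="chr1"):
    return SiteMethylation(chrom, pos, strand, context, mc, total)


class TestCombineCg:
    def test_symmetric_pair_sums(self):
        out = combine_cg_strands([_site(100, "+", mc=3, total=10), _site(101, "-", mc=2, total=10)])
        (merged,) = out
        assert (merged.pos, merged.mc_reads, merged.total_reads) == (100, 5, 20)

    def test_lone_plus_cg_passes_through(self):
        (out,) = combine_cg_strands([_site(100, "+", mc=3, total=10)])
        assert (out.pos, out.strand, out.total_reads) == (100, "+", 10)

    def test_non_cg_never_merged(self):
        sites = [_site(100, "+", "CHH", 1, 10), _site(101, "-", "CHH", 1, 10)]
        assert len(combine_cg_strands(sites)) == 2

    def test_minus_cg_without_mate_passes_through(self):
        (out,) = combine_cg_strands([_site(101, "-", mc=2, total=10)])
        assert out.strand == "-" and out.pos == 101


class TestSiteTest:
    def test_zero_methylated_reads(self):
        assert site_binomial_test(_site(0, mc=0, total=10)) == pytest.approx(1.0)

    def test_fully_methylated_closed_form(self):
        assert site_binomial_test(_site(0, mc=10, total=10), 0.005) == pytest.approx(0.005**10, rel=1e-9)

    def test_partial_matches_enumeration(self):
        p = site_binomial_test(_site(0, mc=2, total=10), 0.005)
        assert p == pytest.approx(binomial_upper_tail(2, 10, Fraction(5, 1000)), rel=1e-9)

    def test_census_applies_bh_across_sites(self):
        sites = [_site(i, mc=m, total=30) for i, m in enumerate([0, 0, 1, 20, 25])]
        flags = call_methylated_sites(sites)
        assert flags == [False, False, False, True, True]

    def test_zero_coverage_is_an_error(self):
        with pytest.raises(ValueError):
            site_binomial_test(_site(0, mc=0, total=0))


class TestBinning:
    @pytest.mark.parametrize(
        "level, expected",
        [
            (0.0, "unmethylated"), (0.0999, "unmethylated"),
            (0.1, "low"), (0.399, "low"),
            (0.4, "moderate"), (0.6, "moderate"),
            (0.6 + 1e-9, "high"), (0.9, "high"),
            (0.9 + 1e-9, "full"), (1.0, "full"),
        ],
    )
    def test_boundaries(self, level, expected):
        assert assign_methylation_bin(level) == expected

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(deadline=None)
    def test_total_on_unit_interval(self, level):
        assert assign_methylation_bin(level) in ("unmethylated", "low", "moderate", "high", "full")

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            assign_methylation_bin(1.2)


class TestGeneLevel:
    def test_weighted_level_example(self, plus_gene):
        sites = [_site(11_000, mc=5, total=10), _site(12_000, mc=0, total=10)]
        gm = gene_weighted_level(plus_gene, sites)
        assert gm.weighted_level == pytest.approx(0.25)
        assert gm.bin == "low"

    def test_invariant_to_order_and_record_splitting(self, plus_gene):
        sites = [_site(11_000, mc=6, total=20), _site(12_000, mc=1, total=10)]
        split = [
            _site(12_000, mc=1, total=10), _site(11_000, mc=2, total=8), _site(11_000, mc=4, total=12),
        ]
        assert gene_weighted_level(plus_gene, sites).weighted_level == pytest.approx(
            gene_weighted_level(plus_gene, split).weighted_level
        )

    def test_no_covered_sites_is_sentinel(self, plus_gene):
        gm = gene_weighted_level(plus_gene, [_site(50, mc=1, total=10)])
        assert gm.bin == "no-data" and gm.weighted_level is None

    def test_context_filter(self, plus_gene):
        sites = [_site(11_000, "+", "CG", 9, 10), _site(12_000, "+", "CHH", 0, 10)]
        assert gene_weighted_level(plus_gene, sites, context="CG").weighted_level == pytest.approx(0.9)
        assert gene_weighted_level(plus_gene, sites).weighted_level == pytest.approx(0.45)


class TestDmc:
    def test_strong_cg_difference_is_dmc(self):
        a, b = [_site(100, mc=9, total=10)], [_site(100, mc=1, total=10)]
        (dmc,) = call_dmcs(a, b, "CG")
        assert dmc.diff == pytest.approx(0.8)
        assert dmc.pvalue == pytest.approx(fisher_two_sided(9, 1, 1, 9), abs=1e-12)

    def test_cg_below_threshold_never_dmc(self):
        # difference 0.3 with overwhelming coverage: significant but below 0.4
        a, b = [_site(100, mc=600, total=1000)], [_site(100, mc=300, total=1000)]
        assert call_dmcs(a, b, "CG") == []

    def test_chh_threshold_is_looser(self):
        a = [_site(100, context="CHH", mc=15, total=30)]
        b = [_site(100, context="CHH", mc=6, total=30)]
        (dmc,) = call_dmcs(a, b, "CHH")
        assert dmc.diff == pytest.approx(0.3)

    def test_unmatched_site_skipped(self):
        assert call_dmcs([_site(100, mc=9, total=10)], [_site(200, mc=0, total=10)], "CG") == []

    def test_dmc_fisher_matches_enumeration(self):
        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(30):
            na, nb = int(rng.integers(5, 101)), int(rng.integers(5, 101))
            ma, mb = int(rng.integers(0, na + 1)), int(rng.integers(0, nb + 1))
            if abs(ma / na - mb / nb) < 0.4:
                continue
            dmcs = call_dmcs([_site(1, mc=ma, total=na)], [_site(1, mc=mb, total=nb)], "CG", pvalue_max=2.0)
            (dmc,) = dmcs
            assert dmc.pvalue == pytest.approx(fisher_two_sided(ma, na - ma, mb, nb - mb), abs=1e-12)


class TestDmr:
    def _dmc(self, pos, direction=1, context="CG"):
        la, lb = (0.9, 0.1) if direction > 0 else (0.1, 0.9)
        return DMC("chr1", pos, context, la, lb, 1e-4)

    def test_three_chained_dmcs_form_dmr(self):
        (dmr,) = call_dmrs([self._dmc(100), self._dmc(150), self._dmc(200)], max_gap=200)
        assert (dmr.start, dmr.end, dmr.n_dmcs) == (100, 201, 3)
        assert dmr.direction == 1 and dmr.mean_diff == pytest.approx(0.8)

    def test_two_dmcs_are_not_enough(self):
        assert call_dmrs([self._dmc(100), self._dmc(150)]) == []

    def test_direction_change_breaks_chain(self):
        dmcs = [self._dmc(100, 1), self._dmc(150, 1), self._dmc(200, -1), self._dmc(250, 1)]
        assert call_dmrs(dmcs, max_gap=200) == []

    def test_large_gap_breaks_chain(self):
        dmcs = [self._dmc(100), self._dmc(150), self._dmc(1000)]
        assert call_dmrs(dmcs, max_gap=200) == []

    def test_contexts_chain_independently(self):
        dmcs = [self._dmc(100), self._dmc(150, context="CHH"), self._dmc(200), self._dmc(300)]
        (dmr,) = call_dmrs(dmcs, max_gap=200)
        assert dmr.context == "CG" and dmr.n_dmcs == 3
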