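import math

import pytest

from hybridepi.allele import (
    AlleleCount,
    ashm_ase_concordance,
    ashm_dhm_association,
    call_ase,
    classify_ashm,
    dhm_ashm_correlation,
    partition_reads,
    read_base_at,
)
from hybridepi.types import AlignedRead, ASHMRecord, ASERecord, GeneModel, SNPRecord
from oracles import binomial_two_sided_half, chi_squared_statistic


def _read(pos, cigar, seq, chrom="chr1", read_id="r"):
    return AlignedRead(read_id, chrom, pos, cigar, seq)


class TestCigarProjection:
    def test_match_block(self):
        read = _read(100, "10M", "ACGTACGTAC")
        assert read_base_at(read, 100) == "A"
        assert read_base_at(read, 109) == "C"
        assert read_base_at(read, 110) is None

    def test_snp_inside_splice_gap_gives_no_base(self):
        """10M5N10M: the 12th reference base of the span falls in the N gap."""
        read = _read(100, "10M5N10M", "A" * 20)
        assert read_base_at(read, 111) is None
        assert read_base_at(read, 115) == "A"  # first base after the gap

    def test_soft_clip_and_insertion_shift_read_offset(self):
        read = _read(100, "3S4M2I4M", "SSSABCDiiEFGH")
        assert read_base_at(read, 100) == "A"
        assert read_base_at(read, 104) == "E"

    def test_deletion_consumes_reference_only(self):
        read = _read(100, "4M2D4M", "ABCDEFGH")
        assert read_base_at(read, 104) is None
        assert read_base_at(read, 106) == "E"

    def test_projection_matches_pysam(self, tmp_path):
        import pysam

        from hybridepi.io import write_sam

        reads = [
            _read(50, "5S10M2D8M3I7M", "X" * 33, read_id="a"),
            _read(120, "10M5N10M", "Y" * 20, read_id="b"),
            _read(7, "25M", "Z" * 25, read_id="c"),
        ]
        path = tmp_path / "proj.sam"
        write_sam(reads, path, {"chr1": 10_000})
        with pysam.AlignmentFile(str(path)) as fh:
            for mine, theirs in zip(reads, fh):
                expected = {
                    ref: mine.seq[q]
                    for q, ref in theirs.get_aligned_pairs()
                    if q is not None and ref is not None
                }
                span = range(mine.pos, mine.pos + 40)
                for ref_pos in span:
                    assert read_base_at(mine, ref_pos) == expected.get(ref_pos)


@pytest.fixture
def snp_gene():
    gene = GeneModel("g1", "chr1", "+", 1000, 2000, exons=[(1000, 2000)], cds=[(1200, 1800)])
    snps = [SNPRecord("chr1", 1300, "A", "G"), SNPRecord("chr1", 1310, "C", "T")]
    return gene, snps


class TestPartitionReads:
    def test_single_snp_votes(self, snp_gene):
        gene, snps = snp_gene
        reads = [
            _read(1295, "10M", "TTTTTATTTT"),  # maternal base at 1300
            _read(1295, "10M", "TTTTTGTTTT"),  # paternal
            _read(1295, "10M", "TTTTTCTTTT"),  # neither parent: ambiguous
            _read(1100, "10M", "T" * 10),      # no SNP covered: ambiguous
        ]
        (count,) = partition_reads(reads, snps, [gene])
        assert (count.maternal_reads, count.paternal_reads, count.ambiguous_reads) == (1, 1, 2)
        assert count.total == 4

    def test_conflicting_multi_snp_read_is_ambiguous(self, snp_gene):
        gene, snps = snp_gene
        seq = list("T" * 20)
        seq[5], seq[15] = "A", "T"  # maternal at 1300, paternal at 1310
        (count,) = partition_reads([_read(1295, "20M", "".join(seq))], snps, [gene])
        assert count.ambiguous_reads == 1 and count.informative == 0

    def test_agreeing_multi_snp_read_counts_once(self, snp_gene):
        gene, snps = snp_gene
        seq = list("T" * 20)
        seq[5], seq[15] = "A", "C"  # both maternal
        (count,) = partition_reads([_read(1295, "20M", "".join(seq))], snps, [gene])
        assert count.maternal_reads == 1

    def test_snp_under_splice_gap_gives_no_vote(self, snp_gene):
        gene, snps = snp_gene
        # spans 1295-1345 with N over both SNPs: read overlaps the gene but votes nothing
        (count,) = partition_reads([_read(1295, "5M20N5M", "T" * 10)], snps, [gene])
        assert count.ambiguous_reads == 1 and count.informative == 0

    def test_cds_count_region_excludes_utr_reads(self, snp_gene):
        gene, snps = snp_gene
        reads = [_read(1050, "10M", "T" * 10)]  # in gene body, outside CDS
        (body,) = partition_reads(reads, snps, [gene], count_region="gene-body")
        (cds,) = partition_reads(reads, snps, [gene], count_region="CDS")
        assert body.total == 1 and cds.total == 0

    def test_partition_conserves_reads_per_gene(self, snp_gene):
        gene, snps = snp_gene
        reads = [
            _read(1295, "10M", "TTTTTATTTT"),
            _read(1305, "10M", "TTTTTTTTTT"),
            _read(100, "10M", "T" * 10),  # outside the gene: not counted
        ]
        (count,) = partition_reads(reads, snps, [gene])
        overlapping = sum(1 for r in reads if r.pos < gene.end and gene.start < r.pos + 10)
        assert count.total == overlapping == 2


class TestClassifyAshm:
    def _count(self, m, p):
        return AlleleCount("g1", "H3K4me3", None, maternal_reads=m, paternal_reads=p)

    @pytest.mark.parametrize(
        "m, p, klass",
        [
            (8, 2, "ASHM-maternal"),
            (2, 8, "ASHM-paternal"),
            (5, 5, "BAHM"),
            (6, 3, "filtered"),   # 9 informative reads: below the >9 filter
            (0, 0, "filtered"),
            (10, 20, "BAHM"),     # ratio exactly 1/3 is biallelic (inclusive)
            (20, 10, "BAHM"),     # ratio exactly 2/3
            (21, 10, "ASHM-maternal"),
            (10, 21, "ASHM-paternal"),
        ],
    )
    def test_classification(self, m, p, klass):
        assert classify_ashm(self._count(m, p), "H3K4me3").klass == klass

    def test_scaling_preserves_class_once_past_filter(self):
        for m, p in ((8, 2), (5, 5), (10, 20)):
            assert (
                classify_ashm(self._count(m, p), "H3K4me3").klass
                == classify_ashm(self._count(10 * m, 10 * p), "H3K4me3").klass
            )


class TestCallAse:
    def test_strong_maternal_bias(self):
        rec = call_ase([(20, 2), (18, 3), (25, 2)], "g1")
        assert rec.log2_mp == pytest.approx(math.log2(64 / 8))
        assert rec.pvalue == pytest.approx(binomial_two_sided_half(63, 70), abs=1e-12)
        assert rec.bias == "maternal"

    def test_weak_fold_change_gives_no_bias(self):
        assert call_ase([(10, 10), (11, 9)], "g1").bias == "none"

    def test_replicate_sign_disagreement_blocks_bias(self):
        rec = call_ase([(9, 1), (1, 9)], "g1")
        assert rec.bias == "none"

    def test_tied_replicate_blocks_bias(self):
        rec = call_ase([(30, 2), (10, 10)], "g1")
        assert rec.bias == "none"

    def test_zero_informative_replicate_excludes_gene(self):
        assert call_ase([(10, 2), (0, 0)], "g1") is None

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            call_ase([(10, 2)], "g1")


def test_ashm_ase_concordance_pairings():
    ashm = [
        ASHMRecord("g1", "H3K4me3", 0.9, 30, "ASHM-maternal"),
        ASHMRecord("g2", "H3K4me3", 0.9, 30, "ASHM-maternal"),
        ASHMRecord("g3", "H3K4me3", 0.5, 30, "BAHM"),
        ASHMRecord("g4", "H3K4me3", 0.1, 30, "ASHM-paternal"),
    ]
    ase = [
        ASERecord("g1", [], 2.0, 1e-4, "maternal"),
        ASERecord("g2", [], -2.0, 1e-4, "paternal"),
        ASERecord("g3", [], 2.0, 1e-4, "maternal"),
    ]
    assert ashm_ase_concordance(ashm, ase) == {
        "concordant": 1, "discordant": 1, "ashm-only": 1, "ase-only": 1,
    }


def test_ashm_dhm_association_matches_hand_chi_squared():
    ashm = []
    # 30 ASHM in DHM_HP, 70 BAHM in DHM_HP, 70 ASHM outside, 330 BAHM outside
    gid = 0
    for n, klass, in_dhm in ((30, "ASHM-maternal", True), (70, "BAHM", True), (70, "ASHM-maternal", False), (330, "BAHM", False)):
        for _ in range(n):
            ashm.append(ASHMRecord(f"g{gid}", "H3K4me3", 0.5, 30, klass))
            gid += 1
    dhm_genes = {r.gene_id for r in ashm[:100]}
    background = {r.gene_id for r in ashm}
    out = ashm_dhm_association(ashm, dhm_genes, background)
    assert out["chi2"] == pytest.approx(chi_squared_statistic([[30, 70], [70, 330]]))
    with pytest.raises(ValueError, match="universe"):
        ashm_dhm_association(ashm, dhm_genes | {"missing"}, background)


def test_dhm_ashm_correlation_extremes():
    fc = {"a": 1.0, "b": 2.0, "c": 3.0}
    assert dhm_ashm_correlation(fc, {"a": 0.1, "b": 0.2, "c": 0.3}) == pytest.approx(1.0)
    assert dhm_ashm_correlation(fc, {"a": 0.9, "b": 0.5, "c": 0.2}) == pytest.approx(-1.0)
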