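# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that make runs bit-reproducible.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GFF3 (1-based inclusive),
1-based SNP/methylation tables and SAM POS are converted at the I/O
boundary. SAM is accepted as text with or without a header; CIGAR ops
M, =, X, I, D, S, N are supported and H/P are rejected with a clear error —
that covers spliced short-read alignments, and hard-clipped or padded
records fall outside the data model. Every writer emits deterministic
column and line order, so identical inputs give byte-identical outputs.

## Differential histone modification

The comparison unit is the *consensus region*: the merged union (≥ 1 bp
overlap, book-ended intervals included) of one mark's peaks across the
three cultivars. Merging was chosen over summit-distance matching because
it is the simplest reproducible rule for deciding that two cultivars' peaks
are "the same" region; its cost is that long overlapping peaks can chain.
Counts are summed across replicates before testing — Fisher's exact test is
a single-table test, so pooling is the only way replicates can enter it —
and per-replicate counts are kept for diagnostics only. The 2×2 table is
[[count_a, lib_a − count_a], [count_b, lib_b − count_b]]; the two-sided
p-value is the sum of all table probabilities no larger than the observed
one. The fold change uses a pseudocount of 0.5 on each proportion
(log2(((a+0.5)/lib_a)/((b+0.5)/lib_b))) to keep zero-count regions finite
and results bit-reproducible. Thresholds: |log2FC| ≥ 1 and raw P < 0.01
(no FDR for regions; FDR is reserved for DEGs). IP counts are used as-is;
input-background subtraction is assumed to have happened upstream at peak
calling, not here.

Region-to-gene annotation uses the region midpoint (synthetic peaks carry
no summit) against promoter-TSS (TSS ± 2,000 bp), TTS window (TTS ± 2,000
bp, chosen symmetric to the promoter definition), exon and intron, in that
priority order; ties between genes are broken by distance to the anchor
(TSS/TTS) and then gene id. Origin attribution maps each significant
hybrid-parent call to the parental difference that would explain it
(H>M from P>M, H<M from P<M, H>P from M>P, H<P from M<P); anything else —
including regions absent from the parental calls — is *novel*. Regions
whose H-vs-M and H-vs-P calls disagree in sign are excluded from the
origin summaries only; their per-record pattern is still reported.

## Allele-level analysis

Diagnostic SNPs are restricted to CDS (where they were screened) while
reads are counted over the gene body by default (`--count-region` switches
to CDS): a read anywhere in the gene body that covers a CDS SNP is
informative. Multi-SNP reads must vote unanimously; conflicting or
non-parental bases make the read ambiguous — conservative by design, and it
exercises the sequencing-error path. The ">9 informative reads" filter is
implemented as ≥ 10. Boundary ratios exactly 1/3 or 2/3 classify as
biallelic (inclusive bounds, i.e. allelic difference strictly above 2-fold
is required for ASHM); ratios are compared as exact rationals so boundary
cases cannot be lost to floating-point rounding.

ASE uses pooled counts for the exact binomial test (p = 0.5) and
per-replicate signs for the consistency requirement; the log2(M/P) effect
size adds +1 to each allele (test statistics use raw counts). A gene with
any zero-informative replicate is excluded. This defined procedure replaces
model-based ASE callers: it is transparent, exact at these depths, and its
components are each verifiable against enumeration oracles.

The ASHM–DHM association is a 1-df chi-squared without continuity
correction on {ASHM, BAHM} × {in DHM_HP, not}; the ASHM–parental-difference
correlation is Spearman with average ranks.

## Methylation

Symmetric CG pairs (+ strand at p, − strand at p+1) are summed into one
record before anything else. Site-level "methylated" calls use a one-sided
binomial test against an error floor of 0.005 (bisulfite non-conversion
plus sequencing error; a documented default, not a measured rate) with
Benjamini–Hochberg correction across sites at FDR 0.05. Gene levels are
weighted (Σ mC / Σ coverage) over gene-body cytosines, all contexts
combined by default with per-context levels always reported alongside,
because the published five-bin gene tables do not state a context
restriction. DMC thresholds are 0.4 (CG) and 0.2 (CHG/CHH) with Fisher
P < 0.05; the level-difference filter is applied before the test, which is
exact (a site failing the difference threshold can never be a DMC). DMRs
chain same-direction DMCs of one context with inter-site gaps ≤ 200 bp
(`--max-gap`; chaining distance is a convention, exposed as a flag); an
intervening opposite-direction DMC breaks the chain; chains need ≥ 3 DMCs.

## Expression and integration

RPKM uses exonic gene length (standard RPKM semantics; the genomic span is
available by summing exons after replacing them with the gene interval).
DEG calling reuses the pooled Fisher engine with BH-FDR < 0.05 and
|log2FC| ≥ 1. This is a deliberate substitution for a negative-binomial
exact test: with pooled counts at the simulated depths the two agree on
strong effects, and sensitivity on strong planted effects — not coefficient
equality with any particular tool — is what the recovery tests check.

A DEG's epigenetic profile records, per layer (H3K4me3, H3K27me3, DNA
methylation), whether the layer varies in the same contrast, its direction,
and its consistency with expression (activating mark: same direction;
repressive layers: opposite). "Methylation varies" means the gene overlaps
a DMR between the contrast members *or* its gene-level weighted difference
is ≥ 0.1; both criteria are also reported separately in the per-gene
tables. Percentages in published-style tables are rendered at two decimals
(one for allele fractions) with round-half-away-from-zero, matching how
such tables are printed.

## Synthetic data: what it emulates

The generator plants, per mark: target genes (peaks), a fraction of
analyzable genes with allele-biased hybrid reads (maternal-read probability
0.85), parent-differential genes at log2 effect 2, and hybrid-specific
("novel") differential genes where the parents agree. Counts are negative
binomial (dispersion 0.1, the overdispersion regime count-based ChIP/RNA
tests assume) with n_replicates = 3 per cultivar; replicate pooling is how
the Fisher engine consumes them. Expression couples positively to the
H3K4me3 level multiplier, negatively to H3K27me3 and to the gene's
methylation level; the coupling strengths are free parameters chosen to
make monotonicity properties testable, not calibrated to any organism.

**Inheritance.** For a parent-differential gene the hybrid adopts the
*higher* parent's level with probability `inheritance_rate` (default 0.7)
and the lower one otherwise. Under the origin-attribution mapping either
outcome yields an "inherited" call in one of the two hybrid contrasts, so
the recovery estimator for the rate is the fraction of planted
parent-differential genes whose hybrid-vs-low-parent contrast is called in
the up direction. The novel class is what populates the "novel" side of
origin summaries.

**Methylation.** Gene baseline levels are drawn from a five-component
mixture so all methylation bins are populated; context multipliers scale
CG > CHG > CHH. A planted DMR converts a run of `sites_per_dmr` (default 5)
consecutive cytosines to one context and sets parent levels 0.05 vs
0.05 + effect (0.5 CG, 0.3 CHG/CHH), hybrid low; consecutive sites keep the
planted region within the caller's chaining distance, mimicking the locally
dense context runs real DMRs sit in. CG sites are emitted on both strands
at ~30× each, so combined CG coverage is ~60×.

**Scale and realism.** One synthetic chromosome per 500 genes with ≥ 5 kb
spacers keeps promoter windows of neighbours disjoint. Reads carry real
bases only at SNP columns (0.5% base-error there feeds the ambiguous
partition) and a constant base elsewhere; there is no fragment-length,
peak-shape or bisulfite-read modeling, no mapping bias, no linked SNPs
and no genuine genome sequence. Passing recovery tests therefore shows the
statistical machinery is correct under the stated noise model — not that
the pipeline is robust to alignment artifacts or reference bias in real
data. The mean of ~100 SNP-informative ChIP reads per analyzable gene
reflects deep ChIP libraries; at much lower depth the 1/3–2/3 window
misclassifies a few percent of biallelic genes by sampling noise alone,
which is a property of the classification rule, not of the implementation.

Recovery checks and the acceptance script run at 2,000 genes, where all
planted-structure estimates are stable in about a minute on one CPU;
smoke and determinism checks use 120–500 genes.

## Known limitations

* Consensus-region matching can chain broad adjacent peaks into one region.
* Fisher on pooled counts ignores replicate-level variance; with few
  replicates and strong effects this is conservative in the mean but can be
  anticonservative for highly variable regions.
* The allele partition has no correction for reference/mapping bias
  (WASP-style filtering is out of scope); with per-site parental bases the
  reference orientation of each SNP is irrelevant to the logic, but not to
  real-world mapping artifacts.
* DMR calling is threshold-based (no beta-binomial shrinkage); boundary
  effects at low coverage are handled only by the coverage filters.
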