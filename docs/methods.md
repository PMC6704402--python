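# Methods

This note records the models, rules and numerical choices behind each
pipeline stage, what the synthetic generators emulate, and the known
limitations of both.

## Coordinate and format conventions

All internal intervals are 0-based half-open. The two deliberate
exceptions are `VariantRecord.pos` (kept 1-based to match VCF) and
partition blocks (1-based inclusive, the RAxML/IQ-TREE convention).
Conversions happen only in `io_formats`: GFF3's 1-based inclusive
coordinates are converted on read and restored on write.

Newick support values are read from the internal-node label position (the
dialect written by IQ-TREE's ultrafast bootstrap and RAxML); values outside
[0, 100] and non-numeric internal labels are rejected. Readers never
repair malformed input — duplicate FASTA ids, ragged orthogroup rows and
out-of-range bedGraph intervals are hard errors — and every writer emits
text its matching reader parses back losslessly.

## Orthogroup filtering and supermatrix construction

An orthogroup is retained when all of the following hold, checked in this
order (rejections report the first failed criterion):

1. single-copy fraction **strictly greater than** 0.80, where the fraction
   is the share of member proteins contributed by taxa holding exactly one
   protein in the group;
2. at least 4 phyla (inclusive);
3. at least 10 species (inclusive).

The strict/inclusive split follows the stated rubric literally ("> 80%"
vs "≥ 4" and "≥ 10"). Filtering operates on the group as read; taxa with
multiple proteins are removed **after** filtering (matching the stated
order of operations), and a pruned group that drops below 10 species is
kept but flagged rather than rejected — the source protocol is silent on
that case, so the pipeline surfaces it instead of deciding.

Concatenation gap-fills absent taxa with `-`, orders blocks
lexicographically by orthogroup id (so output is independent of input
order), and emits a partition file plus per-taxon occupancy. Alignment
(MAFFT) and tree inference (IQ-TREE) are external by design; the module
builds their inputs.

The synthetic orthogroup generator plants a configured number of passing
groups and failing groups that each violate exactly one criterion, so the
filter can be checked against truth labels exactly. Default pool: 30 taxa
in 6 phyla. It does not emulate realistic gene-family size distributions
or correlated taxon sampling; passing tests show the rubric is implemented
exactly, not that the thresholds are optimal for real proteomes.

## Bidirectional ORF screen

`find_orfs` scans all six frames. The default `atg_to_stop` mode reports,
for each in-frame stop, the ORF from the first ATG after the previous stop
(the maximal ATG-anchored ORF); ORFs running into the sequence boundary
are reported and flagged truncated. `stop_to_stop` mode reports full
stop-free regions for sensitivity. `aa_len` excludes the stop, so the
default threshold of 300 aa implies a nucleotide span of at least 900, and
codons containing N count as neither start nor stop. A transcript is
bidirectional-positive when some (+, −) ORF pair overlaps by at least 1 nt
(no minimum is imposed by the screen's definition; configurable);
containment of one span in the other is classed `complete`, anything else
`partial`.

Stranded coverage support is the fraction of each ORF's span with
coverage ≥ 1 on its own strand; an antisense ORF covered on < 10% of its
span is labelled `unsupported_minus`, mirroring the observation that
planted antisense frames of real transcripts showed no transcription
evidence. Convergent 3′-UTR overlap between a + and a − gene model is
reported when the genes' 3′ ends face each other and the annotated UTR
intervals (or, optionally, fixed windows at the 3′ termini) intersect.

The transcript generator builds dual-coding positives constructively:
interior codons are rejection-sampled (budget 10,000) from the set that is
stop-free on both strands, with an ATG/stop arranged on each strand so the
reverse ORF sits fully inside the forward one. Negatives carry a forward
ORF whose aligned reverse frame is salted with reverse-strand stops at
intervals shorter than the detection threshold. Flanks use only G/C
(echoing the organism's high genomic GC), which makes them provably free
of starts and stops. The generator does not emulate introns, UTR sequence
composition, or alternate isoforms; the optional ≥ 95%-identity
pre-clustering used for non-redundancy on real data is therefore untested
against realistic redundancy.

## Ploidy diagnostic

Variants are filtered with coverage ≥ 10, alternate-read count ≥ 3 and,
only when a quality value is present, quality ≥ 20 (the "central quality"
of the original caller is caller-specific and cannot be reproduced
generically, so quality is optional). The band statistic is the fraction
of filtered variants with alternate-allele frequency in the inclusive band
[0.30, 0.70].

The qualitative diploid expectation ("heterozygous sites around 40–60%")
is formalized as the exact binomial band probability at p = 0.5 averaged
over the observed coverage distribution:
E = mean over sites of P(lo ≤ X/c ≤ hi), X ~ Binomial(c, 1/2). At uniform
10× coverage this is 0.890625. The decision rule on
ratio = observed / expected is: ratio < 0.5 → haploid, ratio ≥ 0.75 →
diploid, otherwise ambiguous. The thresholds are configurable and every
report carries all the inputs to the call; the published case (18%
observed against ≈ 89% expected, ratio ≈ 0.20) calls haploid with a wide
margin.

The variant generator draws diploid sites as Binomial(c, 0.5) and haploid
sites as a mixture of error-driven sites (Binomial(c, error_rate),
default 0.01) and fixed differences at frequency ≈ 1. All sites are
conditioned on at least one alternate read, since a caller emits no record
otherwise; at 10× this shifts the diploid band expectation from 0.8906 to
0.8915, well inside the tolerances used. The generator does not model
mapping bias, multi-allelic sites or linked errors.

## Chlamydial HGT classification

Trees are midpoint-rooted (deterministic; no outgroup information is
assumed) with unit branch lengths substituted where lengths are absent.
The recipient clade is the minimal clade containing every Archaeplastida
leaf; its sister's lineage composition identifies the donor (pure
Chlamydiae → sister placement; a mixed sister whose non-recipient members
are all chlamydial → nested placement, recorded distinctly in the audit
trail). Monophyly uses bipartitions and is therefore rooting-independent;
when both a clade and its complement subtend the same unrooted edge (a
bifurcating root), the support of the node matching the queried set is
preferred.

Support classes default to well ≥ 90 and weak ≥ 60. No numeric rule
separating "well" from "weakly" supported is given in the source, so these
are explicit configuration with the 60% display convention as the lower
bound. Sharing categories follow the lineage content of the recipient
clade; `glaucophyte_specific` additionally requires ≥ 2 glaucophyte
species, their monophyly, and intron evidence, which is supplied as a
per-gene boolean derived upstream from gene models rather than recomputed
from sequence. Clades containing non-Archaeplastida intruders (tolerance
default 0) fall into `other`.

The tree generator plants a recipient clade of the requested composition
sister to a chlamydial clade with the requested support, and places
bacterial/eukaryote decoys on long branches (1.0–1.5 substitutions/site
vs 0.05–0.15 inside the planted clades) so the midpoint root falls among
the decoys and never breaks the planted clade. It does not simulate
sequence evolution, gene loss, or contamination inside the recipient
clade, so classifier robustness to those is only bounded by the intruder
tolerance, not measured.

## Time-course differential expression

The experiment design is fixed: six timepoints (1, 8, 14 h after
lights-on; 1, 5, 7 h after dark) × three replicates. Normalization is the
published median-of-ratios formula (factors are medians of per-gene ratios
to the geometric-mean reference over genes nonzero in all samples). Note
the factors are equivariant *relative to each other* when one sample is
rescaled; the geometric-mean reference itself absorbs a common constant.

A gene is differentially expressed iff |log2 fold change| between the
1ALO replicate-mean and any other timepoint's replicate-mean reaches 1.5
**and** the gene has a protein annotation. Fold changes are computed on
normalized replicate means with a pseudocount of 1 (the original
estimator is unstated; the pseudocount gives determinism and zero-count
robustness at the cost of shrinking fold changes for weakly expressed
genes).

`log2(count/factor + 1)` stands in for the estimator-dependent variance
stabilizing transform; it is monotone and empirically flattens the
mean–variance trend across count tiers. Clustering is agglomerative
(average linkage, Euclidean) on per-gene z-scored timepoint means, with
genes sorted lexicographically before linkage so ties break
deterministically; the manual split/join/outlier curation of the original
workflow is replaced by a reproducible cut (cluster count or height).
Peak phase is the argmax timepoint, ties to the earliest, with
declining-from-start (max at 1ALO) and flat profiles flagged.

The count generator uses a negative binomial with var = μ + αμ², gene
base means lognormal(5, 0.7) (median ≈ 150 counts, floored at 10),
per-sample size factors, and planted single-peak profiles at exactly the
configured fold change (default 2.0, both directions). Dispersion
defaults to α = 0.02, a realistic gene-wise dispersion for replicated
synchronized-culture RNA-seq; at that noise the planted labels function
as a near-perfect oracle, which is the regime the recovery suites are
meant to certify. Peak-phase recovery is assessed on up-regulated genes:
a down-regulated single-dip profile has its maximum shared by five
timepoints, so its argmax under noise is undefined by construction. For
clustering tests the generator can instead plant a configured number of
profile prototypes (log2 offsets, z-score-separated by rejection
sampling). The generator does not emulate shared library-preparation
batches, transcript-length effects, or genuinely periodic profiles.

## Problem sizes used in the test and acceptance runs

Recovery suites use 100 orthogroups, 100 random 3-kb sequences plus 20
planted transcripts at 300 aa, 1,000 variants × 100 seeds per ploidy,
200 planted gene trees plus the 35-tree batch, and 20 seeds × 500 genes
(DE) / 320 genes in 40 patterns (clustering). These sizes put every
statistic well past its estimation noise while the full suite runs in a
few seconds.

## Known limitations

* The pipeline never computes alignments, trees, read mappings or variant
  calls; it builds inputs for and consumes outputs of the external tools
  that do.
* The DE stage implements the published filtering rule, not a
  shrinkage-based test; genes with very low counts are conservatively
  attenuated by the pseudocount.
* The HGT classifier assumes the lineage map is total and correct;
  contaminant recipients count as intruders, not evidence.
* The ploidy rule assumes variant frequencies are exchangeable across
  sites; regions of collapsed repeats (frequency ≈ 0.5 in a haploid) are
  not modelled and would inflate the band.
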