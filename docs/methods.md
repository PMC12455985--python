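# Methods

## The problem and the data model

A single diploid individual is sampled at passage 0 (primary tissue), and
replicate cultures are sequenced again after 5 and 10 passages; optionally a
high-fidelity long-read sample of the same individual is included. After
joint genotyping, every sample has a call at every retained SNP site. The
package's central container (`CallSet`) stores the ordered sample list, one
record per site (chromosome, 1-based position, ref/alt alleles, QUAL, the
seven site-level annotations QD/FS/MQ/SOR/MQRankSum/ReadPosRankSum/DP, and a
filter-label set) and one genotype per sample (allele pair, phase flag,
FORMAT DP and GQ). Coordinates are 1-based everywhere; there is no internal
0-based layer, since all inputs and outputs (VCF, GFF3) are 1-based.
Genotypes keep their written order and phase, but every comparison uses the
unordered allele pair: `0|1` and `1|0` are the same genotype. Only GT/DP/GQ
are modeled per sample; other FORMAT fields are ignored on read and not
re-emitted. Multi-allelic SNP records are kept as-is — the recoding scheme
(below) covers allele indices up to 3, so they are part of the analysis.

htslib stores INFO floats in single precision, so the reader normalises
floats to six significant digits; everything the package itself writes uses
at most six significant digits (annotations rounded to 3 decimals, QUAL to
1), making `read(write(cs)) == cs` exact on the modeled field set.

## Filtering

Three stages, in the order a joint-genotyping pipeline applies them:

1. **SNP selection** keeps records whose ref and every alt are single
   nucleotides (multi-allelic SNPs retained, indels/MNPs dropped).
2. **Hard filters** evaluate the seven conditions
   `QD < 2.0`, `FS > 60.0`, `MQ < 40.0`, `SOR > 3.0`, `MQRankSum < −12.5`,
   `ReadPosRankSum < −8.0`, `QUAL < 30.0` independently, with strict
   comparisons exactly as written. A condition on an absent annotation never
   triggers — rank-sum annotations are undefined at sites without
   heterozygous calls, and failing them would mass-drop hom-alt sites.
   Failed sites are labeled (QD, FS, MQ, SOR, MQRS, RPRS, QUAL) in the
   FILTER set rather than deleted; `drop_failed=True` removes them. Because
   the verdict is recomputed from the annotations, the operation is
   idempotent.
3. **Cohort filters**: sites are removed when `INFO/DP < min_depth` or
   `> max_depth` (sites lacking INFO/DP are removed and counted, not fatal),
   then kept iff `MAF > maf_min` and `F_MISSING ≤ miss_max`.

MAF is allele-based: the frequency of the least frequent allele among all
called (non-missing) alleles at the site, taking the minimum over alleles
with nonzero count at multi-allelic sites. This deliberately assigns MAF 1.0
(not 0) to sites where every sample is hom-alt — such cohort-fixed sites
represent reference-assembly alleles absent from the individual and must
survive filtering in a single-individual design. F_MISSING is the fraction
of samples with a missing genotype.

Depth bounds, `maf_min` and `miss_max` are deliberately explicit
configuration (no universal defaults exist). When unspecified, the package
derives `min_depth = ⌈mean site DP / 3⌉` and `max_depth = 2 · mean site DP`
from the callset itself and uses `maf_min = 0.05`,
`miss_max = 0.125` (at most one of eight samples missing). All four values
are echoed into the callset provenance, which is persisted as
`##passage_stability_cmd=` header lines in every VCF the package writes.

## Passage analysis

**Fixed vs. variable.** A site is *fixed* iff every sample's genotype is
non-missing and identical; any disagreement or any missing call makes it
variable. Missingness is already bounded upstream by the F_MISSING filter,
so treating missing as "not fixed" is conservative and cheap to reason
about. `|fixed| + |variable| = N` always.

**Private sites.** Site *i* is private to sample *s* iff *g(i, s)* is
non-missing and no other sample carries the same unordered genotype there.
Missing genotypes are never private and never "match" anything.

**Deviant sites.** Per sample, the variable sites where it departs from the
site's consensus. The consensus (modal) genotype is the most frequent
non-missing genotype *provided it occurs at least twice*; ties among
repeated genotypes are broken by the smallest recode value (then
lexicographically, for full determinism). When no genotype repeats, the site
has no consensus and every sample is deviant there; a missing genotype is
always deviant. The count-≥-2 requirement is what makes the chain
**private ⊆ deviant ⊆ variable** hold universally: without it, a genotype
that is simultaneously unique and modal (e.g. three samples `0/1, 1/1, 1/2`)
would be private but not deviant. This deviant-site definition is this
package's operationalisation of "sites other than the shared heterozygous
background"; a `--deviant-mode`-style alternative (difference against the
reference sample) is available via `diff_vs_reference`.

**Recoding.** Unordered genotypes map to
`{0,0}→0, {0,1}→1, {1,1}→2, {0,2}→3, {1,2}→4, {2,2}→5, {0,3}→6`; any other
pair — including missing and anything involving allele indices beyond the
mapping — maps to a sentinel (−1) with a logged warning. The mapping is
order-insensitive and bijective onto 0–6.

**Summary table.** Per sample: median DP and GQ over its non-missing calls
(even counts: midpoint of the central pair); deviant and private counts;
deviant count as a percentage of the genome size (4 decimals); counts of
deviant genotypes equal to {0,1} and of those neither {0,1} nor {1,1}
(missing genotypes fall in the latter bucket); the "other" count as a
percentage of retained sites (4 decimals; this ratio has no stable
conventional scaling across reports and is excluded from external checks);
and, for non-reference samples, the number of sites whose genotype
differs from the passage-0 sample with its percentage of retained sites (2
decimals). One-sided missingness counts as a difference, double missingness
does not, so the difference count is symmetric and zero on the diagonal.
All printed percentages round half-to-even at the stated precision.

**Private-call quality.** For a sample and metric (DP or GQ), the package
compares the metric at the sample's private sites against all its other
retained sites (both groups restricted to non-missing calls with a
non-missing metric) with a two-sided Mann-Whitney U. For pooled sizes
n₁+n₂ ≤ 12 the null is enumerated over all C(n₁+n₂, n₁) assignments of the
pooled midranks — exact, and valid under ties, where the classical exact
distribution is not. Larger samples use the normal approximation with tie
correction and continuity correction. The two-sample formulation (private
vs. all other sites, rather than a one-sample test against a grand mean) is
the package's reading of "different from the average"; it is the variant
that remains well-defined under ties and unequal group sizes.

## Genome and annotation metrics

QV = −10·log₁₀(error) and error = 10^(−QV/10); the pair is an exact inverse
to 1e−9 relative tolerance on (0, 100]. Heterozygosity density is
het-fraction × 1000 (sites per kb). Nx is the length of the sequence at
which the descending cumulative length first reaches x% of the total, Lx its
1-based rank; GC is computed over non-N residues and the N rate per 100 kb.
Chromosomes with length ≥ 30 Mb are macrochromosomes (the boundary side is a
package choice, configurable), the rest micro. Gene summaries parse GFF3
via gffutils: per gene, the longest isoform by summed exon length (ties by
transcript ID) is retained; gene length is the gene-feature span (end −
start + 1); introns are the gaps between consecutive exons, with overlapping
or unordered exons a fatal error naming the transcript. Gene density divides
the class's gene count by its summed chromosome length in Mb; no per-gene
overlap resolution is attempted, matching the qualitative claims the
metrics serve.

## The simulator

`scenario_study()` returns the default configuration: one passage-0 sample
plus a HiFi-like sample (both passage 0), three passage-5 and four
passage-10 replicates; founder heterozygosity 0.2% (Bernoulli per bp); depth
Poisson(27) per call; GQ = 99 minus a small Poisson jitter (median 99).
Each replicate lineage independently accumulates Poisson(μ·L·passage) novel
mutations at uniform positions: at a hom-ref position the sample becomes het
with the site's first alternate allele; at a founder het site the mutation
picks uniformly among loss to either homozygote or a heterozygote with a
novel allele. Replicates are independent lineages from passage 0 by default
(the real split schedule of replicate flasks is unknown); a
`shared_history_passages` knob lets a passage group share its first k
passages of mutation history. Artifact calls hit a configurable fraction of
emitted sites per sample: a spurious heterozygote involving a novel allele
index (capped at 3, so overflowing codes exercise the recode sentinel), with
depth shifted by `artifact_depth_shift` (floored at 1) and GQ redrawn from a
low-mean truncated normal. Missing genotypes are injected per call. INFO
annotations and QUAL are drawn from configurable clipped normals whose
defaults sit well inside the hard-filter pass region; they exist to exercise
the filters, not to model a variant caller faithfully. Everything flows from
one integer seed: identical seeds give byte-identical VCF output.

μ is an order-of-magnitude placeholder (default 1e−6 per bp per passage):
no reference expectation exists for somatic mutation rates in avian
fibroblast culture, and the default is chosen so that a 1 Mb simulated
genome yields a handful-to-tens of mutations per replicate — enough to test
detection without swamping the founder signal.

What the generator does *not* emulate: read-level errors and mapping (no
FASTQ/BAM), linked artifacts (each artifact is independent), indels/CNVs or
large rearrangements (karyotype-scale stability is assumed), and any
population genetics of the culture. Passing tests therefore demonstrate
correctness of the analysis logic under the stated statistical structure,
not robustness to upstream calling pathologies.

The annotation generator places non-overlapping genes (1 + Poisson(4) exons
of 100–300 bp; intron lengths exponential around the class mean, floored at
31 bp) on two 40 Mb macrochromosomes and eight 5 Mb microchromosomes, with
gene quotas chosen to realise a target micro:macro density ratio exactly
and the intron-length ratio in expectation.

## Problem sizes and numerical choices

The validation suites run on scaled-down genomes chosen as the package's
test conditions: 1 Mb (≈2,000 segregating sites) for recall of true
mutations as private sites, 5 Mb (≈10,000 sites) for the filter-oracle
equivalence sweep, and 4 Mb with artifact rate 0.001 and depth shift −10
for the detection-power study (50 seeds), where the passage-0 sample's
private set is essentially its artifact set. Exact/approximate rank-sum
agreement is checked at the enumeration crossover. Medians over even counts
use the central-pair midpoint; all report rounding is round-half-to-even;
degenerate inputs (empty callsets, all-missing sites, zero-gene classes,
empty rank-sum groups) either produce defined absent values or raise a
named error, as documented per function.

## Known limitations

- The deviant-site ("other than shared heterozygous") definition is one
  defensible operationalisation among several; results of that column
  should be compared across samples, not across tools.
- MAF semantics intentionally differ from bcftools at monomorphic hom-alt
  sites (see Filtering); users replicating a bcftools expression exactly
  should pre-split such sites.
- The per-class gene density ignores overlapping genes and unplaced
  scaffolds.
- The exact rank-sum enumeration is O(C(n₁+n₂, n₁)) and is capped at pooled
  size 12 by default.
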