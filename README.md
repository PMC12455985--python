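# passage-stability

Tools for asking whether serially passaged cell cultures stay genomically
stable. Cryobanking and *ex situ* conservation increasingly rely on cultured
fibroblasts, yet there is no consensus on how many passages are "safe" before
cells accumulate mutations. Given a jointly genotyped, multi-sample SNP
callset from one diploid individual — a passage-0 sample, replicate flasks at
later passages, and optionally a long-read reference sample — this package
answers: which variant sites are shared by every sample, which genotypes are
private to a single replicate, how many positions each replicate differs from
passage 0, and whether the private calls look like real mutations or like
low-quality calling artifacts.

It is a library first (importable API plus `examples/`), with a thin
`passage-stability` CLI for the file-level steps (filtering, simulation,
reports).

## What it computes

For a callset with samples *s = 1..S* and retained sites *i = 1..N*, with
unordered genotypes *g(i, s)*:

- **Filtering** — SNP record selection, the standard seven per-site hard
  filters (`QD < 2.0`, `FS > 60.0`, `MQ < 40.0`, `SOR > 3.0`,
  `MQRankSum < −12.5`, `ReadPosRankSum < −8.0`, `QUAL < 30.0`; conditions on
  absent annotations never trigger), then cohort filters
  `min_depth ≤ INFO/DP ≤ max_depth` and `MAF > maf_min ∧ F_MISSING ≤ miss_max`.
- **Site partition** — a site is *fixed* iff all *g(i, s)* are non-missing and
  identical; else *variable*.
- **Private sites** — site *i* is private to *s* iff *g(i, s)* is non-missing
  and equals no other sample's genotype at *i*.
- **Per-sample table** — median DP/GQ, deviant-site and private-site counts,
  genotype composition of the deviant set (recoded
  0/0→0, 0/1→1, 1/1→2, 0/2→3, 1/2→4, 2/2→5, 0/3→6, anything else → sentinel),
  deviant sites as a fraction of the genome, and the count/percentage of
  genotype differences against the passage-0 reference.
- **Private-call quality** — two-sided Mann-Whitney U comparing DP (or GQ) at
  a sample's private sites against all its other sites; exact enumeration of
  the null for pooled sizes ≤ 12 (valid under ties), otherwise the normal
  approximation with tie and continuity correction.
- **Genome metrics** — QV = −10·log₁₀(error rate) and its inverse,
  heterozygous-sites-per-kb, N50/L50/N90/L90/GC, macro- vs. microchromosome
  classification at a 30 Mb cutoff, and per-class gene density / gene length /
  intron length from GFF3.
- **Simulation** — a seeded generator producing the whole experiment (founder
  heterozygosity 0.2%, passage design 1 + 3 + 4 replicates plus an optional
  HiFi-like sample, depth ~Poisson(27), GQ saturating at 99, optional artifact
  calls with depressed DP/GQ, missing genotypes) together with a complete
  truth table, so every analysis can be validated without any data download.

## Worked example

```bash
python examples/simulate_passages.py
```

prints (abridged):

```
samples: HiFi, P0, P5.1, P5.2, P5.3, P10.1, P10.2, P10.3, P10.4
sites: 2544  fixed: 2015  variable: 529

sample  median_dp  median_gq  nonfixed_count  private_count  ...  diff_vs_p0  pct_diff_vs_p0
P0      27.0       99.0       0               0                   -           -
P5.1    27.0       99.0       53              53                  53          2.08
P10.1   27.0       99.0       90              90                  90          3.54
```

The founder's ~2,000 heterozygous sites are fixed across all samples; each
replicate's private count grows with passage number because its lineage
accumulated Poisson(μ·L·passage) novel mutations, and `diff_vs_p0` counts the
genotype differences against the passage-0 sample (here 2–4% of retained
sites). `examples/private_site_quality.py` shows the companion quality check:
with artifact calls injected at 0.1% of sites, the private-vs-other depth and
GQ comparisons reject decisively (p ≪ 0.05) for every sample.

The same steps as shell commands:

```bash
passage-stability simulate --seed 3 --genome-length 1000000 --out-prefix run
passage-stability filter run.vcf run.filt.vcf --report run.report.tsv
passage-stability table run.filt.vcf --reference-sample P0 --genome-size 1000000
passage-stability compare-quality run.filt.vcf --sample P10.1 --metric depth
```

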