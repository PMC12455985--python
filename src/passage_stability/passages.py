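"""Per-passage genomic-stability analysis of a filtered multi-sample callset.

Given a jointly genotyped, quality-filtered SNP callset from replicate cell
cultures of a single individual (passage 0 plus replicate flasks at later
passages), this module partitions sites into cross-sample fixed vs. variable,
detects per-sample private and deviant genotypes, recodes genotypes into the
standard small-integer scheme, builds the per-sample summary table, counts
genotype differences against the passage-0 reference, and compares depth/GQ
of private calls against the sample's remaining calls with a rank-sum test.

Definitions
-----------
fixed site
    Every sample carries the same non-missing unordered genotype.  In a
    single-individual design these are mostly true heterozygous sites of the
    founder, represented by one allele in the reference assembly.
private site (per sample)
    The sample's genotype is non-missing and found in no other sample.
deviant site (per sample)
    A variable site where the sample departs from the site's modal genotype.
    The mode is the most frequent non-missing genotype, provided it occurs at
    least twice (ties among such genotypes broken by smallest recode value,
    then lexicographically); when no genotype repeats there is no consensus
    and every sample is deviant.  A missing genotype is always deviant.  These
    rules make private ⊆ deviant ⊆ variable hold for every sample.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from statistics import median

from .callset import CallSet
from .stats import RankSumResult, rank_sum_test

__all__ = [
    "SENTINEL",
    "RECODE_MAP",
    "SitePartition",
    "PassageStatsRow",
    "recode_genotype",
    "recode_matrix",
    "classify_sites",
    "private_sites",
    "deviant_sites",
    "diff_vs_reference",
    "passage_table",
    "compare_private_quality",
    "percent_of_total",
    "percent_of_genome",
]

logger = logging.getLogger(__name__)

#: Code assigned to genotypes outside the defined recode mapping (incl. missing).
SENTINEL = -1

#: Order-insensitive genotype recoding used in the per-sample analyses.
RECODE_MAP: dict[tuple[int, int], int] = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 1): 2,
    (0, 2): 3,
    (1, 2): 4,
    (2, 2): 5,
    (0, 3): 6,
}


def recode_genotype(g: tuple[int, int] | None) -> int:
    """Map an unordered genotype to its small-integer code.

    ``g`` is an allele-index pair in any order, or ``None`` for missing.  Any
    pair outside the defined mapping (including missing) returns
    :data:`SENTINEL` and logs a warning.
    """
    if g is None:
        logger.warning("recoding missing genotype -> sentinel")
        return SENTINEL
    a, b = g
    key = (a, b) if a <= b else (b, a)
    code = RECODE_MAP.get(key)
    if code is None:
        logger.warning("genotype %s outside recode mapping -> sentinel", key)
        return code if code is not None else SENTINEL
    return code


def recode_matrix(cs: CallSet):
    """sites × samples integer matrix of genotype codes (SENTINEL where unmapped)."""
    import numpy as np

    mat = np.full((cs.n_sites, cs.n_samples), SENTINEL, dtype=np.int8)
    for i, site in enumerate(cs.sites):
        for j, call in enumerate(site.calls):
            g = call.unordered
            if g is not None:
                mat[i, j] = RECODE_MAP.get(g if g[0] <= g[1] else (g[1], g[0]),
                                           SENTINEL)
    return mat


@dataclass(frozen=True)
class SitePartition:
    """Indices of cross-sample fixed vs. variable sites."""

    fixed_sites: frozenset[int]
    variable_sites: frozenset[int]

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_sites)

    @property
    def n_variable(self) -> int:
        return len(self.variable_sites)


def classify_sites(cs: CallSet) -> SitePartition:
    """Partition sites into fixed (identical non-missing genotype in every
    sample) vs. variable (everything else, including any missingness)."""
    if cs.n_samples < 2:
        raise ValueError("site classification requires at least 2 samples")
    fixed, variable = set(), set()
    for i, site in enumerate(cs.sites):
        gts = {c.unordered for c in site.calls}
        if None not in gts and len(gts) == 1:
            fixed.add(i)
        else:
            variable.add(i)
    return SitePartition(frozenset(fixed), frozenset(variable))


def private_sites(cs: CallSet, sample: str) -> set[int]:
    """Sites where ``sample``'s non-missing genotype occurs in no other sample."""
    j = cs.sample_index(sample)
    out = set()
    for i, site in enumerate(cs.sites):
        g = site.calls[j].unordered
        if g is None:
            continue
        if all(site.calls[k].unordered != g
               for k in range(cs.n_samples) if k != j):
            out.add(i)
    return out


def _mode_key(item):
    # sort by descending count, then recode value with sentinel last, then
    # genotype tuple for full determinism
    g, count = item
    code = RECODE_MAP.get(g, SENTINEL)
    return (-count, code == SENTINEL, code, g)


def _modal_genotype(site) -> tuple[int, int] | None:
    counts = Counter(c.unordered for c in site.calls if c.unordered is not None)
    if not counts:
        return None
    g, n = min(counts.items(), key=_mode_key)
    return g if n >= 2 else None


def deviant_sites(
    cs: CallSet, sample: str, partition: SitePartition | None = None
) -> set[int]:
    """Variable sites where ``sample`` departs from the modal genotype.

    Missing genotypes are deviant; when no genotype occurs twice at a site
    there is no mode and every sample is deviant there.
    """
    j = cs.sample_index(sample)
    if partition is None:
        partition = classify_sites(cs)
    out = set()
    for i in partition.variable_sites:
        site = cs.sites[i]
        g = site.calls[j].unordered
        if g is None:
            out.add(i)
            continue
        mode = _modal_genotype(site)
        if mode is None or g != mode:
            out.add(i)
    return out


def diff_vs_reference(cs: CallSet, sample: str, reference_sample: str) -> int:
    """Number of sites where the two samples' unordered genotypes differ.

    A one-sided missing genotype counts as a difference; both missing does
    not.  Symmetric in its two arguments; zero against itself.
    """
    j = cs.sample_index(sample)
    r = cs.sample_index(reference_sample)
    n = 0
    for site in cs.sites:
        a = site.calls[j].unordered
        b = site.calls[r].unordered
        if a != b:
            n += 1
    return n


def percent_of_total(count: int, total: int, ndigits: int = 2) -> float:
    """100*count/total rounded half-to-even to ``ndigits`` decimals."""
    return round(100.0 * count / total, ndigits)


def percent_of_genome(count: int, genome_size: int) -> float:
    """Site count as a percentage of genome size, 4 decimals."""
    return round(100.0 * count / genome_size, 4)


@dataclass(frozen=True)
class PassageStatsRow:
    """One sample's row of the per-passage summary table.

    ``nonfixed_count`` counts the sample's deviant sites, ``private_count``
    its private sites; ``het01_count``/``other_count`` break deviant sites
    down by recoded genotype ({0,1} het vs. anything that is neither {0,1}
    nor {1,1}).  ``pct_nonfixed`` = 100*other_count/total retained sites;
    this column has no stable conventional scaling across published reports
    and is excluded from external checks.  ``diff_vs_p0`` fields are absent
    (None) on the reference row.
    """

    sample: str
    median_dp: float | None
    median_gq: float | None
    nonfixed_count: int
    private_count: int
    pct_of_genome: float
    het01_count: int
    other_count: int
    pct_nonfixed: float
    diff_vs_p0: int | None
    pct_diff_vs_p0: float | None


TABLE_COLUMNS = [
    "sample", "median_dp", "median_gq", "nonfixed_count", "private_count",
    "pct_of_genome", "het01_count", "other_count", "pct_nonfixed",
    "diff_vs_p0", "pct_diff_vs_p0",
]


def passage_table(
    cs: CallSet, reference_sample: str, genome_size: int
) -> list[PassageStatsRow]:
    """Per-sample summary rows over all retained sites.

    Medians of DP/GQ are taken over the sample's non-missing calls (even
    counts: midpoint of the central pair).  Percentages use genome_size for
    the genome fraction (4 decimals) and the total retained site count for
    the difference-vs-reference percentage (2 decimals), rounding
    half-to-even.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    ref_idx = cs.sample_index(reference_sample)  # raises if absent
    total = cs.n_sites
    partition = classify_sites(cs)
    rows = []
    for j, sample in enumerate(cs.samples):
        dps = [s.calls[j].depth for s in cs.sites
               if not s.calls[j].is_missing and s.calls[j].depth is not None]
        gqs = [s.calls[j].quality for s in cs.sites
               if not s.calls[j].is_missing and s.calls[j].quality is not None]
        deviant = deviant_sites(cs, sample, partition)
        private = private_sites(cs, sample)
        het01 = other = 0
        for i in deviant:
            g = cs.sites[i].calls[j].unordered
            if g == (0, 1):
                het01 += 1
            elif g != (1, 1):
                other += 1
        if j == ref_idx:
            diff = pct_diff = None
        else:
            diff = diff_vs_reference(cs, sample, reference_sample)
            pct_diff = percent_of_total(diff, total, 2) if total else 0.0
        rows.append(PassageStatsRow(
            sample=sample,
            median_dp=float(median(dps)) if dps else None,
            median_gq=float(median(gqs)) if gqs else None,
            nonfixed_count=len(deviant),
            private_count=len(private),
            pct_of_genome=percent_of_genome(len(deviant), genome_size),
            het01_count=het01,
            other_count=other,
            pct_nonfixed=percent_of_total(other, total, 4) if total else 0.0,
            diff_vs_p0=diff,
            pct_diff_vs_p0=pct_diff,
        ))
    return rows


def table_to_tsv(rows: list[PassageStatsRow]) -> str:
    """Render summary rows as TSV (header + one line per sample)."""
    def fmt(v):
        return "-" if v is None else str(v)

    lines = ["\t".join(TABLE_COLUMNS)]
    for r in rows:
        lines.append("\t".join(fmt(getattr(r, c)) for c in TABLE_COLUMNS))
    return "\n".join(lines) + "\n"


def compare_private_quality(
    cs: CallSet, sample: str, metric: str = "depth"
) -> RankSumResult:
    """Rank-sum comparison of ``metric`` at the sample's private sites vs.
    all its other retained sites.

    ``metric`` is ``"depth"`` (FORMAT DP) or ``"quality"`` (FORMAT GQ).  Both
    groups use the sample's non-missing calls with a non-missing metric
    value.  Exact null by enumeration for small pooled sizes, else normal
    approximation with tie correction (see :mod:`passage_stability.stats`).
    """
    if metric not in ("depth", "quality"):
        raise ValueError("metric must be 'depth' or 'quality'")
    j = cs.sample_index(sample)
    private = private_sites(cs, sample)
    x, y = [], []
    for i, site in enumerate(cs.sites):
        call = site.calls[j]
        if call.is_missing:
            continue
        v = call.depth if metric == "depth" else call.quality
        if v is None:
            continue
        (x if i in private else y).append(v)
    if not x:
        raise ValueError(f"no private sites with non-missing {metric} "
                         f"for sample {sample!r}")
    if not y:
        raise ValueError(f"no non-private sites with non-missing {metric} "
                         f"for sample {sample!r}")
    return rank_sum_test(x, y)
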