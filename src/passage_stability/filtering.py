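"""Site selection and filtering for joint SNP callsets.

Implements the standard three-stage post-calling pipeline for a jointly
genotyped cohort: SNP record selection, GATK-style per-site hard filters on
the seven quality annotations, and bcftools-style cohort filters on site
depth, minor allele frequency and genotype missingness.

Hard-filter semantics follow the GATK convention: each condition is evaluated
independently, a condition on an absent annotation never triggers (rank-sum
annotations are undefined at sites without heterozygous calls), and failed
sites are labeled rather than deleted unless ``drop_failed`` is requested.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .callset import CallSet, VariantSite

__all__ = [
    "HardFilterThresholds",
    "CohortFilterParams",
    "FilterReport",
    "select_snps",
    "apply_hard_filters",
    "cohort_depth_filter",
    "cohort_maf_missing_filter",
    "site_maf",
    "site_missing_fraction",
]


@dataclass(frozen=True)
class HardFilterThresholds:
    """Per-site hard-filter cutoffs (GATK VariantFiltration conventions).

    A site fails a label when the strict comparison below holds; all
    comparisons are strict, matching the usual filter expressions::

        QD < qd_min        FS > fs_max         MQ < mq_min
        SOR > sor_max      MQRankSum < mqrs_min
        ReadPosRankSum < rprs_min               QUAL < qual_min
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    sor_max: float = 3.0
    mqrs_min: float = -12.5
    rprs_min: float = -8.0
    qual_min: float = 30.0


@dataclass(frozen=True)
class CohortFilterParams:
    """Cohort-level site filters.

    ``min_depth``/``max_depth`` bound the site INFO/DP (summed cohort depth);
    a site is removed when ``DP < min_depth`` or ``DP > max_depth``.
    ``maf_min`` and ``miss_max`` implement ``MAF > maf_min &&
    F_MISSING <= miss_max``.
    """

    min_depth: int = 1
    max_depth: int = 10**9
    maf_min: float = 0.05
    miss_max: float = 0.125

    def __post_init__(self):
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.miss_max <= 1.0:
            raise ValueError("miss_max must be in [0, 1]")

    @classmethod
    def from_mean_depth(cls, cs: CallSet, maf_min: float = 0.05,
                        miss_max: float = 0.125) -> "CohortFilterParams":
        """Depth bounds derived from the callset: [ceil(mean/3), 2*mean].

        Mean is taken over sites carrying INFO/DP; with no such site the
        depth bounds are left permissive.
        """
        dps = [s.info["DP"] for s in cs.sites if "DP" in s.info]
        if not dps:
            return cls(maf_min=maf_min, miss_max=miss_max)
        mean = sum(dps) / len(dps)
        return cls(
            min_depth=math.ceil(mean / 3.0),
            max_depth=int(2.0 * mean),
            maf_min=maf_min,
            miss_max=miss_max,
        )


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step."""

    step: str
    sites_in: int = 0
    sites_out: int = 0
    fail_counts: Counter = field(default_factory=Counter)

    def to_tsv(self) -> str:
        lines = [f"step\t{self.step}", f"sites_in\t{self.sites_in}",
                 f"sites_out\t{self.sites_out}"]
        for label, n in sorted(self.fail_counts.items()):
            lines.append(f"fail_{label}\t{n}")
        return "\n".join(lines) + "\n"


def select_snps(cs: CallSet) -> CallSet:
    """Keep sites where ref and every alt are single nucleotides.

    Multi-allelic SNPs are retained; indels and MNPs are dropped.  Order is
    preserved.
    """
    kept = [s for s in cs.sites if s.is_snp]
    return cs.with_sites(kept, f"select_snps kept={len(kept)}/{len(cs.sites)}")


def hard_filter_labels(site: VariantSite, t: HardFilterThresholds) -> set[str]:
    """Labels of the hard-filter conditions that trigger at ``site``.

    Absent annotations never trigger; a missing QUAL never triggers.
    """
    info = site.info
    labels: set[str] = set()
    if "QD" in info and info["QD"] < t.qd_min:
        labels.add("QD")
    if "FS" in info and info["FS"] > t.fs_max:
        labels.add("FS")
    if "MQ" in info and info["MQ"] < t.mq_min:
        labels.add("MQ")
    if "SOR" in info and info["SOR"] > t.sor_max:
        labels.add("SOR")
    if "MQRankSum" in info and info["MQRankSum"] < t.mqrs_min:
        labels.add("MQRS")
    if "ReadPosRankSum" in info and info["ReadPosRankSum"] < t.rprs_min:
        labels.add("RPRS")
    if site.qual is not None and site.qual < t.qual_min:
        labels.add("QUAL")
    return labels


def apply_hard_filters(
    cs: CallSet,
    thresholds: HardFilterThresholds | None = None,
    drop_failed: bool = False,
) -> tuple[CallSet, FilterReport]:
    """Label (or drop) sites failing the per-site hard filters.

    Each retained site's ``filter`` set is replaced by the labels of the
    triggered conditions (empty = PASS), so the operation is idempotent.
    """
    t = thresholds or HardFilterThresholds()
    report = FilterReport("hard_filters", sites_in=cs.n_sites)
    out = []
    for site in cs.sites:
        labels = hard_filter_labels(site, t)
        for label in labels:
            report.fail_counts[label] += 1
        if labels and drop_failed:
            continue
        new = site.copy()
        new.filter = labels
        out.append(new)
    report.sites_out = len(out)
    note = f"hard_filters drop_failed={drop_failed} kept={len(out)}/{cs.n_sites}"
    return cs.with_sites(out, note), report


def cohort_depth_filter(
    cs: CallSet, params: CohortFilterParams
) -> tuple[CallSet, FilterReport]:
    """Remove sites with INFO/DP outside [min_depth, max_depth].

    Sites lacking INFO/DP are removed and counted separately (label
    ``DP_absent``), not fatal.
    """
    report = FilterReport("cohort_depth", sites_in=cs.n_sites)
    out = []
    for site in cs.sites:
        dp = site.info.get("DP")
        if dp is None:
            report.fail_counts["DP_absent"] += 1
            continue
        if dp < params.min_depth or dp > params.max_depth:
            report.fail_counts["DP"] += 1
            continue
        out.append(site.copy())
    report.sites_out = len(out)
    note = (f"cohort_depth min={params.min_depth} max={params.max_depth} "
            f"kept={len(out)}/{cs.n_sites}")
    return cs.with_sites(out, note), report


def site_maf(site: VariantSite) -> float | None:
    """Minor allele frequency over called alleles at ``site``.

    Frequency of the least frequent allele among all non-missing called
    alleles; for multi-allelic sites, the minimum over alleles with nonzero
    count.  ``None`` when every genotype is missing.
    """
    counts = Counter()
    for call in site.calls:
        g = call.unordered
        if g is not None:
            counts[g[0]] += 1
            counts[g[1]] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    return min(counts.values()) / total


def site_missing_fraction(site: VariantSite) -> float:
    """Fraction of samples with a missing genotype at ``site``."""
    if not site.calls:
        return 0.0
    return sum(c.is_missing for c in site.calls) / len(site.calls)


def cohort_maf_missing_filter(
    cs: CallSet, params: CohortFilterParams
) -> tuple[CallSet, FilterReport]:
    """Keep sites with ``MAF > maf_min`` and ``F_MISSING <= miss_max``.

    Sites where every genotype is missing have undefined MAF and are removed
    (counted under ``MAF_undefined``).
    """
    report = FilterReport("cohort_maf_missing", sites_in=cs.n_sites)
    out = []
    for site in cs.sites:
        maf = site_maf(site)
        if maf is None:
            report.fail_counts["MAF_undefined"] += 1
            continue
        if not maf > params.maf_min:
            report.fail_counts["MAF"] += 1
            continue
        if not site_missing_fraction(site) <= params.miss_max:
            report.fail_counts["F_MISSING"] += 1
            continue
        out.append(site.copy())
    report.sites_out = len(out)
    note = (f"cohort_maf_missing maf>{params.maf_min} miss<={params.miss_max} "
            f"kept={len(out)}/{cs.n_sites}")
    return cs.with_sites(out, note), report


def filter_pipeline(
    cs: CallSet,
    thresholds: HardFilterThresholds | None = None,
    params: CohortFilterParams | None = None,
) -> tuple[CallSet, list[FilterReport]]:
    """Full pipeline: select SNPs, hard filters (dropping failures), depth,
    then MAF/missingness.  Cohort depth bounds default to
    :meth:`CohortFilterParams.from_mean_depth` of the post-hard-filter set.
    """
    snps = select_snps(cs)
    hard, r1 = apply_hard_filters(snps, thresholds, drop_failed=True)
    if params is None:
        params = CohortFilterParams.from_mean_depth(hard)
    depth, r2 = cohort_depth_filter(hard, params)
    final, r3 = cohort_maf_missing_filter(depth, params)
    return final, [r1, r2, r3]
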