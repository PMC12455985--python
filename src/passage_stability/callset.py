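"""In-memory model of a multi-sample SNP callset.

The central container is :class:`CallSet`: an ordered list of samples plus an
ordered list of :class:`VariantSite` records, each carrying one
:class:`SampleGenotype` per sample.  All coordinates are 1-based as in VCF;
there is no internal 0-based layer.  Genotypes are stored as ordered allele
pairs with a phased flag, but every comparison in the package operates on the
unordered allele pair (``0|1`` and ``1|0`` are the same genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "INFO_KEYS",
    "SampleGenotype",
    "VariantSite",
    "CallSet",
    "validate_callset",
]

#: Site-level INFO annotations modeled by the package (GATK emission names).
INFO_KEYS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum", "DP")


@dataclass(frozen=True, slots=True)
class SampleGenotype:
    """One sample's call at one site.

    ``allele_a``/``allele_b`` are allele indices into ``[ref] + alts``
    (0 = ref), or ``None`` for a missing allele.  ``depth`` (FORMAT DP) and
    ``quality`` (FORMAT GQ, Phred, capped at 99 by the caller) are ``None``
    when absent in the source VCF.
    """

    allele_a: int | None
    allele_b: int | None
    phased: bool = False
    depth: int | None = None
    quality: int | None = None

    @property
    def is_missing(self) -> bool:
        """A genotype is missing iff either allele index is missing."""
        return self.allele_a is None or self.allele_b is None

    @property
    def unordered(self) -> tuple[int, int] | None:
        """Order-insensitive genotype, or ``None`` if missing."""
        if self.is_missing:
            return None
        a, b = self.allele_a, self.allele_b
        return (a, b) if a <= b else (b, a)


@dataclass(slots=True)
class VariantSite:
    """One locus with site-level annotations and per-sample calls.

    ``info`` holds only the keys in :data:`INFO_KEYS` that were present in the
    source; an absent annotation is absent from the mapping, never 0.
    ``filter`` is the set of failed hard-filter labels; the empty set means
    PASS.  ``calls`` aligns positionally with ``CallSet.samples``.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    qual: float | None = None
    info: dict[str, float] = field(default_factory=dict)
    filter: set[str] = field(default_factory=set)
    calls: list[SampleGenotype] = field(default_factory=list)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def copy(self) -> "VariantSite":
        return replace(
            self, alts=list(self.alts), info=dict(self.info),
            filter=set(self.filter), calls=list(self.calls),
        )


@dataclass(slots=True)
class CallSet:
    """Ordered samples + ordered variant sites + a provenance log.

    ``provenance`` records the operations applied to this callset, one string
    per step; writers emit it as ``##passage_stability_cmd=`` header lines.
    """

    samples: list[str]
    sites: list[VariantSite] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in callset") from None

    def with_sites(self, sites: list[VariantSite], note: str | None = None) -> "CallSet":
        """New CallSet sharing samples, with ``note`` appended to provenance."""
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return CallSet(samples=list(self.samples), sites=sites, provenance=prov)


def validate_callset(cs: CallSet) -> list[str]:
    """Report invariant violations; an empty list means the callset is valid.

    Checks: unique sample names, sites sorted by (chrom, pos) with chromosomes
    contiguous, call/sample alignment, allele indices in range, non-empty alts
    distinct from ref, positive positions.
    """
    problems: list[str] = []
    if len(set(cs.samples)) != len(cs.samples):
        problems.append("duplicate sample identifiers")

    seen_chroms: dict[str, int] = {}
    prev: tuple[int, int] | None = None
    for site in cs.sites:
        where = f"{site.chrom}:{site.pos}"
        if site.pos < 1:
            problems.append(f"non-positive position at {where}")
        if not site.alts:
            problems.append(f"no alt alleles at {where}")
        elif site.ref in site.alts:
            problems.append(f"alt equals ref at {where}")
        if len(site.calls) != cs.n_samples:
            problems.append(f"call/sample mismatch at {where}")
        for sample, call in zip(cs.samples, site.calls):
            for allele in (call.allele_a, call.allele_b):
                if allele is not None and not 0 <= allele < site.n_alleles:
                    problems.append(f"allele index out of range at {where} ({sample})")
            if call.depth is not None and call.depth < 0:
                problems.append(f"negative depth at {where} ({sample})")
            if call.quality is not None and not 0 <= call.quality <= 99:
                problems.append(f"GQ outside [0, 99] at {where} ({sample})")
        if site.chrom not in seen_chroms:
            seen_chroms[site.chrom] = len(seen_chroms)
        key = (seen_chroms[site.chrom], site.pos)
        if prev is not None and key < prev:
            problems.append(f"unsorted site at {where}")
        prev = key
    return problems
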