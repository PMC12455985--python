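"""VCF 4.2 reading and writing for :class:`~passage_stability.callset.CallSet`.

Backed by pysam/htslib; plain and bgzipped VCF are both supported.  Only the
fields the analyses consume are modeled: GT/DP/GQ per sample, the seven
site-level INFO annotations, QUAL and FILTER.  Other FORMAT/INFO content is
ignored on read and not re-emitted.

htslib stores INFO floats in single precision, so floats are normalised to six
significant digits on read; any value written with at most six significant
digits round-trips exactly.
"""

from __future__ import annotations

import os

import pysam

from .callset import CallSet, INFO_KEYS, SampleGenotype, VariantSite

__all__ = ["read_callset", "write_callset", "VcfFormatError", "PROVENANCE_KEY"]

#: Header key used to persist the provenance log.
PROVENANCE_KEY = "passage_stability_cmd"


class VcfFormatError(ValueError):
    """Raised for VCF input that violates the package's contract."""


def _norm_float(x) -> float:
    # float32 -> shortest-ish decimal: 6 significant digits covers everything
    # the package itself writes.
    return float(f"{float(x):.6g}")


def read_callset(path: str | os.PathLike) -> CallSet:
    """Read a multi-sample VCF into a :class:`CallSet`.

    Raises :class:`VcfFormatError` if GT is not declared in FORMAT, sample
    names are duplicated, or records are not coordinate-sorted (chromosomes
    contiguous, positions non-decreasing).
    """
    try:
        vcf_file = pysam.VariantFile(os.fspath(path))
    except ValueError as exc:  # htslib rejects e.g. duplicated sample names
        raise VcfFormatError(f"{path}: {exc}") from exc
    with vcf_file as vcf:
        if "GT" not in vcf.header.formats:
            raise VcfFormatError(f"{path}: no GT field declared in FORMAT")
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise VcfFormatError(f"{path}: duplicated sample names")

        provenance = [
            str(rec.value)
            for rec in vcf.header.records
            if rec.type == "GENERIC" and rec.key == PROVENANCE_KEY
        ]

        sites: list[VariantSite] = []
        seen_chroms: dict[str, int] = {}
        prev: tuple[int, int] | None = None
        for rec in vcf:
            if rec.chrom not in seen_chroms:
                seen_chroms[rec.chrom] = len(seen_chroms)
            key = (seen_chroms[rec.chrom], rec.pos)
            if prev is not None and key < prev:
                raise VcfFormatError(
                    f"{path}: unsorted record at {rec.chrom}:{rec.pos}"
                )
            prev = key

            info: dict[str, float] = {}
            for k in INFO_KEYS:
                if k in rec.info:
                    v = rec.info[k]
                    info[k] = int(v) if k == "DP" else _norm_float(v)

            filters = set(rec.filter.keys()) - {"PASS"}

            calls = []
            for name in samples:
                fmt = rec.samples[name]
                gt = fmt.get("GT", (None, None))
                if gt is None or len(gt) < 2:
                    gt = (None, None)
                dp = fmt.get("DP")
                gq = fmt.get("GQ")
                calls.append(
                    SampleGenotype(
                        allele_a=gt[0],
                        allele_b=gt[1],
                        phased=bool(fmt.phased),
                        depth=None if dp is None else int(dp),
                        quality=None if gq is None else int(gq),
                    )
                )

            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=list(rec.alts or ()),
                    qual=None if rec.qual is None else _norm_float(rec.qual),
                    info=info,
                    filter=filters,
                    calls=calls,
                )
            )

    return CallSet(samples=samples, sites=sites, provenance=provenance)


def _build_header(cs: CallSet) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for k in INFO_KEYS:
        typ = "Integer" if k == "DP" else "Float"
        header.add_line(f'##INFO=<ID={k},Number=1,Type={typ},Description="{k}">')
    filter_labels: set[str] = set()
    for site in cs.sites:
        filter_labels |= site.filter
    for label in sorted(filter_labels):
        header.add_line(f'##FILTER=<ID={label},Description="Failed {label} hard filter">')
    contigs: dict[str, None] = {}
    for site in cs.sites:
        contigs.setdefault(site.chrom, None)
    for name in contigs:
        header.add_line(f"##contig=<ID={name}>")
    for entry in cs.provenance:
        header.add_line(f"##{PROVENANCE_KEY}={entry}")
    for sample in cs.samples:
        header.add_sample(sample)
    return header


def write_callset(cs: CallSet, path: str | os.PathLike) -> None:
    """Write ``cs`` to ``path`` as VCF (bgzipped if the name ends in .gz).

    Round-trip contract: ``read_callset(write_callset(cs))`` equals ``cs`` on
    every modeled field, provided floats carry at most six significant digits.
    """
    path = os.fspath(path)
    mode = "wz" if path.endswith(".gz") else "w"
    header = _build_header(cs)
    with pysam.VariantFile(path, mode, header=header) as out:
        for site in cs.sites:
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=[site.ref, *site.alts],
            )
            rec.qual = site.qual
            for k, v in site.info.items():
                rec.info[k] = v
            if site.filter:
                for label in sorted(site.filter):
                    rec.filter.add(label)
            else:
                rec.filter.add("PASS")
            for name, call in zip(cs.samples, site.calls):
                fmt = rec.samples[name]
                fmt["GT"] = (call.allele_a, call.allele_b)
                fmt.phased = call.phased
                if call.depth is not None:
                    fmt["DP"] = call.depth
                if call.quality is not None:
                    fmt["GQ"] = call.quality
            out.write(rec)
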