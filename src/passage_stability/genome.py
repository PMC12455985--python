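"""Assembly and annotation summary metrics.

Self-contained computations around a genome assembly and its gene
annotation: Phred QV ↔ error-rate conversion, heterozygosity density,
contiguity statistics (Nx/Lx, GC, N-rate), macro/micro chromosome
classification at a configurable size cutoff (30 Mb default, as in avian
karyotype work), and per-class gene/intron summaries from GFF3.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

__all__ = [
    "AssemblyStats",
    "ChromosomeClass",
    "GeneClassSummary",
    "MACRO_CUTOFF",
    "qv_to_error",
    "error_to_qv",
    "het_per_kb",
    "assembly_stats",
    "classify_chromosomes",
    "gene_class_summary",
    "read_sequence_lengths",
]

#: Default macro/micro chromosome size boundary (bp); >= cutoff is macro.
MACRO_CUTOFF = 30_000_000


def qv_to_error(qv: float) -> float:
    """Phred-scaled consensus quality to base-call error rate: 10^(-qv/10)."""
    if qv < 0:
        raise ValueError("QV must be non-negative")
    return 10.0 ** (-qv / 10.0)


def error_to_qv(err: float) -> float:
    """Error rate to Phred-scaled QV: -10*log10(err); inverse of qv_to_error."""
    if not 0.0 < err <= 1.0:
        raise ValueError("error rate must be in (0, 1]")
    return -10.0 * math.log10(err)


def het_per_kb(het_fraction: float) -> float:
    """Genome-wide heterozygous fraction to heterozygous sites per kb."""
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("heterozygous fraction must be in [0, 1]")
    return het_fraction * 1000.0


@dataclass(frozen=True)
class AssemblyStats:
    """Contiguity summary of an assembly.

    ``gc_percent`` and ``n_per_100kb`` are ``None`` unless residues were
    supplied.
    """

    total_size: int
    n_sequences: int
    n50: int
    l50: int
    n90: int
    l90: int
    gc_percent: float | None = None
    n_per_100kb: float | None = None


def _nx_lx(sorted_desc: list[int], total: int, x: float) -> tuple[int, int]:
    """Length of the sequence at which the descending cumulative sum first
    reaches x% of the total, and its 1-based rank."""
    threshold = total * x / 100.0
    cum = 0
    for rank, length in enumerate(sorted_desc, start=1):
        cum += length
        if cum >= threshold:
            return length, rank
    return sorted_desc[-1], len(sorted_desc)  # pragma: no cover


def assembly_stats(
    lengths: list[int], sequences: list[str] | None = None
) -> AssemblyStats:
    """N50/L50, N90/L90, totals; GC% and Ns per 100 kb when residues given.

    GC is computed over non-N residues; ambiguity codes other than N count as
    non-GC.
    """
    if not lengths:
        raise ValueError("empty assembly: no sequence lengths")
    if any(l <= 0 for l in lengths):
        raise ValueError("sequence lengths must be positive")
    sorted_desc = sorted(lengths, reverse=True)
    total = sum(sorted_desc)
    n50, l50 = _nx_lx(sorted_desc, total, 50)
    n90, l90 = _nx_lx(sorted_desc, total, 90)
    gc = n_rate = None
    if sequences is not None:
        ngc = nn = 0
        for seq in sequences:
            s = seq.upper()
            ngc += s.count("G") + s.count("C")
            nn += s.count("N")
        denom = total - nn
        gc = 100.0 * ngc / denom if denom else 0.0
        n_rate = 100_000.0 * nn / total
    return AssemblyStats(
        total_size=total, n_sequences=len(lengths),
        n50=n50, l50=l50, n90=n90, l90=l90,
        gc_percent=gc, n_per_100kb=n_rate,
    )


@dataclass(frozen=True)
class ChromosomeClass:
    """A named chromosome with its macro/micro class label."""

    name: str
    length: int
    klass: str  # "macro" | "micro"


def classify_chromosomes(
    lengths: dict[str, int], cutoff: int = MACRO_CUTOFF
) -> tuple[list[ChromosomeClass], dict[str, int]]:
    """Classify chromosomes as macro (length >= cutoff) or micro.

    Returns the per-chromosome classes (input order preserved) and the
    per-class counts.  The boundary itself is assigned to macro.
    """
    classes = []
    counts = {"macro": 0, "micro": 0}
    for name, length in lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {name}")
        klass = "macro" if length >= cutoff else "micro"
        counts[klass] += 1
        classes.append(ChromosomeClass(name, length, klass))
    return classes, counts


@dataclass(frozen=True)
class GeneClassSummary:
    """Gene/intron summary for one chromosome class.

    Means are ``None`` when the class has no genes (or, for introns, no
    multi-exon transcript).  ``genes_per_mb`` divides by the summed length of
    the class's chromosomes in Mb.
    """

    klass: str
    gene_count: int
    genes_per_mb: float
    mean_gene_length: float | None
    mean_intron_length: float | None
    mean_exons_per_gene: float | None


def _longest_isoform_exons(db, gene) -> list[tuple[int, int]]:
    """Exons of the gene's longest isoform (summed exon length, ties by
    transcript ID), sorted by start.  Raises on overlapping exons."""
    best = None
    for tx in db.children(gene, level=1):
        exons = sorted(
            (f.start, f.end) for f in db.children(tx, featuretype="exon")
        )
        if not exons:
            continue
        span = sum(e - s + 1 for s, e in exons)
        key = (-span, tx.id)
        if best is None or key < best[0]:
            best = (key, exons, tx.id)
    if best is None:
        return [(gene.start, gene.end)]  # exonless gene: single-block model
    _, exons, tx_id = best
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping exons in transcript {tx_id}")
    return exons


def gene_class_summary(
    gff_path: str | os.PathLike, classes: list[ChromosomeClass]
) -> dict[str, GeneClassSummary]:
    """Per-class gene statistics from a GFF3 annotation.

    Gene length is the gene feature span (end - start + 1, 1-based
    inclusive); intron lengths are the gaps between consecutive exons of the
    gene's longest isoform.  Genes on chromosomes absent from ``classes`` are
    ignored.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            os.fspath(gff_path), ":memory:",
            merge_strategy="create_unique", keep_order=True,
        )
        genes = list(db.features_of_type("gene"))
    except gffutils.exceptions.EmptyInputError:
        db, genes = None, []
    class_of = {c.name: c.klass for c in classes}
    length_of = {"macro": 0, "micro": 0}
    for c in classes:
        length_of[c.klass] += c.length

    acc = {k: {"genes": 0, "gene_len": 0, "introns": 0, "intron_len": 0,
               "exons": 0} for k in ("macro", "micro")}
    for gene in genes:
        klass = class_of.get(gene.seqid)
        if klass is None:
            continue
        exons = _longest_isoform_exons(db, gene)
        a = acc[klass]
        a["genes"] += 1
        a["gene_len"] += gene.end - gene.start + 1
        a["exons"] += len(exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            a["introns"] += 1
            a["intron_len"] += s2 - e1 - 1

    out = {}
    for klass, a in acc.items():
        mb = length_of[klass] / 1e6
        out[klass] = GeneClassSummary(
            klass=klass,
            gene_count=a["genes"],
            genes_per_mb=a["genes"] / mb if mb else 0.0,
            mean_gene_length=a["gene_len"] / a["genes"] if a["genes"] else None,
            mean_intron_length=(a["intron_len"] / a["introns"]
                                if a["introns"] else None),
            mean_exons_per_gene=a["exons"] / a["genes"] if a["genes"] else None,
        )
    return out


def read_sequence_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Sequence lengths from FASTA or a two-column (name, length) table.

    FASTA is detected by a leading '>'; anything else is parsed as
    whitespace-separated name/length lines (``.fai`` files work: extra
    columns are ignored).
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO

        return {rec.id: len(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    lengths = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            lengths[parts[0]] = int(parts[1])
    return lengths
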