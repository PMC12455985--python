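"""Synthetic diploid passage-series callsets with complete ground truth.

The generator emulates the statistical structure of a cell-passage
resequencing experiment on a single diploid individual: a founder genome
with ~0.2% heterozygosity, a passage-0 sample (plus an optional HiFi-like
reference sample), replicate lineages at later passages that independently
accumulate Poisson-distributed novel point mutations, per-sample read depth
around a Poisson mean of 27×, genotype qualities saturating at 99, an
optional fraction of artifact calls with depressed depth and GQ, and missing
genotypes.  Every run returns the full truth bookkeeping (founder
heterozygous sites, per-replicate mutations, injected artifacts) so
downstream analyses can be validated exactly.

A companion generator produces toy chromosome length tables and GFF3 gene
annotations with a controlled micro/macro gene-density ratio and intron
length ratio.

All randomness flows from a single integer seed; identical seeds give
byte-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .callset import CallSet, SampleGenotype, VariantSite

__all__ = [
    "SimConfig",
    "SimTruth",
    "AnnotationSim",
    "simulate_truth",
    "simulate_callset",
    "simulate_annotation",
    "scenario_study",
    "truth_to_tsv",
]

_BASES = "ACGT"

#: INFO annotation sampling parameters: (mean, sd, low clip, high clip).
#: Defaults are centred well inside the hard-filter pass region so that an
#: unstressed simulation retains essentially every site.
DEFAULT_INFO_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "QD": (20.0, 5.0, 2.5, 40.0),
    "FS": (5.0, 5.0, 0.0, 50.0),
    "MQ": (60.0, 3.0, 45.0, 70.0),
    "SOR": (1.0, 0.5, 0.0, 2.8),
    "MQRankSum": (0.0, 1.0, -4.0, 4.0),
    "ReadPosRankSum": (0.0, 1.0, -4.0, 4.0),
    "QUAL": (800.0, 150.0, 35.0, 5000.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the passage-series simulation.

    ``passages`` lists (label, passage_number, n_replicates); the default is
    the study design of one passage-0 sample, three passage-5 replicates and
    four passage-10 replicates, with an extra HiFi-like reference sample
    (also passage 0) when ``include_hifi``.  ``mu`` is the per-bp,
    per-passage novel mutation rate — an order-of-magnitude placeholder, as
    no reference expectation exists for avian fibroblast culture.
    ``shared_history_passages`` lets replicate lineages share their first k
    passages of mutation history (0 = fully independent lineages).
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 4
    het_rate: float = 0.002
    passages: tuple[tuple[str, int, int], ...] = (
        ("P0", 0, 1), ("P5", 5, 3), ("P10", 10, 4),
    )
    include_hifi: bool = True
    mu: float = 1e-6
    artifact_rate: float = 0.0
    depth_lambda: float = 27.0
    artifact_depth_shift: int = -10
    artifact_gq_mean: float = 40.0
    artifact_gq_sd: float = 15.0
    gq_max: int = 99
    gq_drop_rate: float = 0.3
    missing_rate: float = 0.0
    shared_history_passages: int = 0
    seed: int = 0
    info_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INFO_PARAMS)
    )

    def __post_init__(self):
        for name in ("het_rate", "artifact_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")

    @property
    def sample_names(self) -> list[str]:
        names = ["HiFi"] if self.include_hifi else []
        for label, _, n_rep in self.passages:
            if n_rep == 1:
                names.append(label)
            else:
                names.extend(f"{label}.{i}" for i in range(1, n_rep + 1))
        return names

    @property
    def sample_passages(self) -> dict[str, int]:
        out = {"HiFi": 0} if self.include_hifi else {}
        for label, p, n_rep in self.passages:
            if n_rep == 1:
                out[label] = p
            else:
                for i in range(1, n_rep + 1):
                    out[f"{label}.{i}"] = p
        return out

    @property
    def chrom_lengths(self) -> dict[str, int]:
        """Deterministic macro/micro-like length mix summing to genome_length."""
        n = self.n_chromosomes
        weights = np.array([(n - i) ** 2 + 1 for i in range(n)], dtype=float)
        raw = np.floor(self.genome_length * weights / weights.sum()).astype(int)
        raw = np.maximum(raw, 1)
        raw[0] += self.genome_length - int(raw.sum())
        return {f"chr{i + 1}": int(raw[i]) for i in range(n)}


def scenario_study(**overrides) -> SimConfig:
    """The packaged default configuration emulating the study design.

    One passage-0 sample plus a HiFi-like sample, 3 passage-5 and 4
    passage-10 replicates, founder heterozygosity 0.2%, depth 27×, GQ
    saturating at 99.  The genome is scaled down to 1 Mb by default; pass
    ``genome_length`` to change it.
    """
    return SimConfig(**overrides)


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    ``het_sites`` maps founder heterozygous global positions (1-based) to the
    founder genotype; ``per_sample_mutations`` maps each sample to
    position -> post-mutation genotype; ``artifact_sites`` maps each sample
    to the positions that received a spurious call.  Per sample, mutation
    and artifact positions are disjoint.
    """

    genome_length: int
    het_sites: dict[int, tuple[int, int]]
    per_sample_mutations: dict[str, dict[int, tuple[int, int]]]
    artifact_sites: dict[str, set[int]]

    @property
    def universe(self) -> list[int]:
        """Sorted positions that are non-hom-ref in at least one sample."""
        pos = set(self.het_sites)
        for muts in self.per_sample_mutations.values():
            pos |= muts.keys()
        return sorted(pos)


# legal moves applied by a novel mutation; allele 2 denotes the site's
# novel allele
_HET_MOVES = [(0, 0), (1, 1), (0, 2), (1, 2)]


def simulate_truth(cfg: SimConfig) -> SimTruth:
    """Draw founder heterozygous sites, per-lineage mutations and artifacts.

    Founder het sites are Bernoulli(het_rate) per bp.  Each replicate lineage
    accumulates Poisson(mu * L * passage_number) novel mutations at uniform
    positions; a mutation at a hom-ref position creates a heterozygote with
    the site's first alternate allele, while one at a founder het site picks
    uniformly among the legal moves (loss to either homozygote, or a
    heterozygote involving a novel allele).  With
    ``shared_history_passages`` = k > 0, mutations of the first
    min(k, passage) passages are shared by all replicates of a passage group.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    L = cfg.genome_length

    het_pos = np.flatnonzero(rng.random(L) < cfg.het_rate) + 1
    het_sites = {int(p): (0, 1) for p in het_pos}

    def draw_mutations(n_expected_passages: int) -> dict[int, tuple[int, int]]:
        n = rng.poisson(cfg.mu * L * n_expected_passages)
        muts: dict[int, tuple[int, int]] = {}
        for pos in rng.integers(1, L + 1, size=n):
            pos = int(pos)
            if pos in muts:
                continue
            if pos in het_sites:
                muts[pos] = _HET_MOVES[rng.integers(0, len(_HET_MOVES))]
            else:
                muts[pos] = (0, 1)
        return muts

    per_sample: dict[str, dict[int, tuple[int, int]]] = {}
    if cfg.include_hifi:
        per_sample["HiFi"] = {}
    for label, passage, n_rep in cfg.passages:
        shared_p = min(cfg.shared_history_passages, passage)
        shared = draw_mutations(shared_p) if shared_p else {}
        for i in range(1, n_rep + 1):
            name = label if n_rep == 1 else f"{label}.{i}"
            own = draw_mutations(passage - shared_p)
            merged = dict(shared)
            merged.update(own)
            per_sample[name] = merged

    universe = sorted(set(het_sites) | {p for m in per_sample.values() for p in m})
    artifacts: dict[str, set[int]] = {}
    for name in cfg.sample_names:
        mask = rng.random(len(universe)) < cfg.artifact_rate
        chosen = {universe[i] for i in np.flatnonzero(mask)}
        artifacts[name] = chosen - per_sample[name].keys()

    return SimTruth(
        genome_length=L,
        het_sites=het_sites,
        per_sample_mutations=per_sample,
        artifact_sites=artifacts,
    )


def _global_to_chrom(cfg: SimConfig):
    """Mapping from 1-based global position to (chrom, 1-based local pos)."""
    names, bounds = [], []
    offset = 0
    for name, length in cfg.chrom_lengths.items():
        names.append(name)
        bounds.append(offset)
        offset += length
    starts = np.array(bounds)

    def convert(pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(starts, pos - 1, side="right")) - 1
        return names[i], pos - int(starts[i])

    return convert


def simulate_callset(truth: SimTruth, cfg: SimConfig) -> CallSet:
    """Assemble the multi-sample callset implied by ``truth``.

    One record is emitted per position that is non-hom-ref in at least one
    sample.  Depth is Poisson(depth_lambda); GQ saturates at ``gq_max`` with
    a small Poisson downward jitter.  Artifact calls receive a spurious
    heterozygote involving a novel allele index (capped at 3, so overflowing
    genotype codes exercise the recoding sentinel), depth shifted by
    ``artifact_depth_shift`` (floored at 1) and a degraded GQ.  Missing
    genotypes are injected per call at ``missing_rate``.  Site-level INFO
    annotations and QUAL are drawn from the configured clipped normal
    distributions (rounded so that VCF round-trips are exact).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    samples = cfg.sample_names
    universe = truth.universe
    n_sites, n_samples = len(universe), len(samples)
    convert = _global_to_chrom(cfg)

    dp = rng.poisson(cfg.depth_lambda, size=(n_sites, n_samples))
    gq = cfg.gq_max - rng.poisson(cfg.gq_drop_rate, size=(n_sites, n_samples))
    np.clip(gq, 0, cfg.gq_max, out=gq)
    art_gq = np.clip(
        np.rint(rng.normal(cfg.artifact_gq_mean, cfg.artifact_gq_sd,
                           size=(n_sites, n_samples))),
        0, cfg.gq_max,
    ).astype(int)
    missing = rng.random((n_sites, n_samples)) < cfg.missing_rate

    info_draws = {}
    for key, (mean, sd, lo, hi) in cfg.info_params.items():
        vals = np.clip(rng.normal(mean, sd, size=n_sites), lo, hi)
        info_draws[key] = np.round(vals, 1 if key == "QUAL" else 3)
    # FS is non-negative by construction
    if "FS" in info_draws:
        info_draws["FS"] = np.abs(info_draws["FS"])

    art_partner = rng.integers(0, 2, size=(n_sites, n_samples))
    base_choice = rng.integers(0, 4, size=n_sites)

    sites: list[VariantSite] = []
    for i, pos in enumerate(universe):
        founder = truth.het_sites.get(pos, (0, 0))
        gts: list[tuple[int, int] | None] = []
        max_allele = 1  # allele 1 exists at every emitted site
        for j, name in enumerate(samples):
            g = truth.per_sample_mutations[name].get(pos, founder)
            max_allele = max(max_allele, g[0], g[1])
            gts.append(g)
        for j, name in enumerate(samples):
            if pos in truth.artifact_sites[name]:
                novel = min(max_allele + 1, 3)
                max_allele = max(max_allele, novel)
                gts[j] = (int(art_partner[i, j]), novel)

        calls = []
        info_dp = 0
        for j in range(n_samples):
            if missing[i, j]:
                calls.append(SampleGenotype(None, None))
                continue
            is_art = pos in truth.artifact_sites[samples[j]]
            d = int(dp[i, j])
            if is_art:
                d = max(1, d + cfg.artifact_depth_shift)
                q = int(art_gq[i, j])
            else:
                q = int(gq[i, j])
            info_dp += d
            a, b = gts[j]
            calls.append(SampleGenotype(a, b, depth=d, quality=q))

        ref = _BASES[base_choice[i]]
        alt_pool = [b for b in _BASES if b != ref]
        alts = alt_pool[:max_allele]
        chrom, local = convert(pos)
        info = {k: float(v[i]) for k, v in info_draws.items() if k != "QUAL"}
        info["DP"] = info_dp
        sites.append(VariantSite(
            chrom=chrom, pos=local, ref=ref, alts=alts,
            qual=float(info_draws["QUAL"][i]) if "QUAL" in info_draws else None,
            info=info, calls=calls,
        ))

    prov = [f"simulate seed={cfg.seed} L={cfg.genome_length} "
            f"het={cfg.het_rate} mu={cfg.mu} artifact={cfg.artifact_rate}"]
    return CallSet(samples=samples, sites=sites, provenance=prov)


def truth_to_tsv(truth: SimTruth) -> str:
    """Truth table as TSV: sample, global position, class, genotype."""
    lines = ["sample\tposition\tclass\tgenotype"]
    for pos in sorted(truth.het_sites):
        a, b = truth.het_sites[pos]
        lines.append(f"founder\t{pos}\thet\t{a}/{b}")
    for sample in sorted(truth.per_sample_mutations):
        for pos in sorted(truth.per_sample_mutations[sample]):
            a, b = truth.per_sample_mutations[sample][pos]
            lines.append(f"{sample}\t{pos}\tmutation\t{a}/{b}")
    for sample in sorted(truth.artifact_sites):
        for pos in sorted(truth.artifact_sites[sample]):
            lines.append(f"{sample}\t{pos}\tartifact\t.")
    return "\n".join(lines) + "\n"


@dataclass
class AnnotationSim:
    """A synthetic annotation: chromosome lengths, GFF3 lines and truth."""

    chrom_lengths: dict[str, int]
    gff_lines: list[str]
    truth: dict[str, float]

    def write_gff(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write("\n".join(self.gff_lines) + "\n")

    def write_lengths(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            for name, length in self.chrom_lengths.items():
                fh.write(f"{name}\t{length}\n")


def simulate_annotation(
    density_ratio: float = 2.0,
    intron_scale: float = 0.5,
    n_genes: int = 2000,
    n_macro: int = 2,
    macro_length: int = 40_000_000,
    n_micro: int = 8,
    micro_length: int = 5_000_000,
    macro_intron_mean: float = 1500.0,
    exon_mean_extra: float = 4.0,
    seed: int = 0,
) -> AnnotationSim:
    """Toy genome + GFF3 with controlled micro/macro contrasts.

    ``density_ratio`` is the target micro:macro genes-per-Mb ratio and
    ``intron_scale`` the target micro:macro mean-intron-length ratio.  Genes
    are placed non-overlapping; exons per gene are 1 + Poisson, exon lengths
    uniform in [100, 300], intron lengths exponential around the class mean
    (floored at 31 bp).  The returned truth records the target and realised
    ratios.
    """
    if density_ratio <= 0 or intron_scale <= 0:
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng([seed, 3])
    chroms: dict[str, int] = {}
    for i in range(n_macro):
        chroms[f"macro{i + 1}"] = macro_length
    for i in range(n_micro):
        chroms[f"micro{i + 1}"] = micro_length

    lm = n_micro * micro_length
    lM = n_macro * macro_length
    n_micro_genes = int(round(n_genes * density_ratio * lm
                              / (density_ratio * lm + lM)))
    n_macro_genes = n_genes - n_micro_genes

    quotas: dict[str, int] = {name: 0 for name in chroms}
    for klass, count, n_chr in (("macro", n_macro_genes, n_macro),
                                ("micro", n_micro_genes, n_micro)):
        for g in range(count):
            quotas[f"{klass}{g % n_chr + 1}"] += 1

    lines = ["##gff-version 3"]
    intron_sums = {"macro": [0, 0], "micro": [0, 0]}  # total_len, count
    gene_id = 0
    for name, length in chroms.items():
        klass = "macro" if name.startswith("macro") else "micro"
        intron_mean = (macro_intron_mean if klass == "macro"
                       else macro_intron_mean * intron_scale)
        cursor = 1
        for _ in range(quotas[name]):
            gene_id += 1
            start = cursor + int(rng.integers(200, 1000))
            n_exons = 1 + int(rng.poisson(exon_mean_extra))
            exon_lens = rng.integers(100, 301, size=n_exons)
            intron_lens = (np.maximum(
                np.rint(rng.exponential(intron_mean, size=n_exons - 1)), 31
            ).astype(int) if n_exons > 1 else np.array([], dtype=int))
            exons = []
            p = start
            for k in range(n_exons):
                exons.append((p, p + int(exon_lens[k]) - 1))
                p = exons[-1][1] + 1
                if k < n_exons - 1:
                    p += int(intron_lens[k])
            end = exons[-1][1]
            if end > length:
                raise ValueError(f"chromosome {name} too short for its quota")
            gid, tid = f"gene{gene_id}", f"tx{gene_id}"
            lines.append(f"{name}\t.\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
            lines.append(f"{name}\t.\tmRNA\t{start}\t{end}\t.\t+\t.\t"
                         f"ID={tid};Parent={gid}")
            for s, e in exons:
                lines.append(f"{name}\t.\texon\t{s}\t{e}\t.\t+\t.\tParent={tid}")
            intron_sums[klass][0] += int(intron_lens.sum())
            intron_sums[klass][1] += len(intron_lens)
            cursor = end + 1

    def mean_intron(klass):
        tot, n = intron_sums[klass]
        return tot / n if n else float("nan")

    truth = {
        "target_density_ratio": density_ratio,
        "target_intron_scale": intron_scale,
        "n_macro_genes": n_macro_genes,
        "n_micro_genes": n_micro_genes,
        "realized_density_ratio": ((n_micro_genes / (lm / 1e6))
                                   / (n_macro_genes / (lM / 1e6))
                                   if n_macro_genes else float("nan")),
        "realized_intron_scale": mean_intron("micro") / mean_intron("macro"),
    }
    return AnnotationSim(chrom_lengths=chroms, gff_lines=lines, truth=truth)
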