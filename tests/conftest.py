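"""Shared builders for callset tests."""

from __future__ import annotations

import numpy as np
import pytest

from passage_stability.callset import CallSet, SampleGenotype, VariantSite


def gt(text: str, depth: int | None = None, quality: int | None = None) -> SampleGenotype:
    """Parse '0/1', '1|0' or './.' into a SampleGenotype."""
    phased = "|" in text
    a, b = text.replace("|", "/").split("/")
    return SampleGenotype(
        allele_a=None if a == "." else int(a),
        allele_b=None if b == "." else int(b),
        phased=phased,
        depth=depth,
        quality=quality,
    )


def make_callset(
    genotypes: list[list[str]],
    samples: list[str] | None = None,
    n_alts: int | None = None,
    depths: list[list[int]] | None = None,
    quals: list[list[int]] | None = None,
) -> CallSet:
    """CallSet on one chromosome with sites at positions 100, 200, ...

    ``genotypes[i][j]`` is sample j's genotype string at site i.  ``n_alts``
    defaults to the largest allele index seen at each site (min 1).
    """
    n_samples = len(genotypes[0]) if genotypes else 0
    samples = samples or [f"S{j + 1}" for j in range(n_samples)]
    alt_bases = ["T", "G", "C"]
    sites = []
    for i, row in enumerate(genotypes):
        calls = []
        max_allele = 1
        for j, text in enumerate(row):
            call = gt(
                text,
                depth=depths[i][j] if depths else 30,
                quality=quals[i][j] if quals else 99,
            )
            for al in (call.allele_a, call.allele_b):
                if al is not None:
                    max_allele = max(max_allele, al)
            calls.append(call)
        k = n_alts if n_alts is not None else max_allele
        sites.append(VariantSite(
            chrom="chr1", pos=100 * (i + 1), ref="A",
            alts=(alt_bases * 2)[:k], calls=calls,
        ))
    return CallSet(samples=samples, sites=sites)


def random_callset(rng: np.random.Generator, n_sites: int = 30,
                   n_samples: int = 5) -> CallSet:
    """Small random callset with missing calls and up to 4 alleles."""
    genos = []
    for _ in range(n_sites):
        row = []
        for _ in range(n_samples):
            if rng.random() < 0.08:
                row.append("./.")
            else:
                a, b = rng.integers(0, 4, size=2)
                row.append(f"{min(a, b)}/{max(a, b)}")
        genos.append(row)
    return make_callset(genos, n_alts=3)


@pytest.fixture
def toy_trio():
    """Three samples, genotypes covering fixed/variable/private cases."""
    return make_callset([
        ["0/1", "0/1", "0/1"],   # fixed het
        ["0/1", "0/1", "1/1"],   # variable, private for S3
        ["0/1", "1/1", "1/2"],   # all three private
        ["1/1", "1/1", "1/1"],   # fixed hom-alt
        ["0/1", "0/1", "./."],   # variable through missingness
    ])
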