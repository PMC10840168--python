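"""Shared fixtures: small synthetic bundles and toy annotations."""

from __future__ import annotations

import numpy as np
import pytest

from glknet import GeneratorConfig, GenomeAnnotation, Gene, generate_dataset


def small_config(**overrides) -> GeneratorConfig:
    """A reduced study: quick to generate, still carries every planted effect."""
    base = dict(
        n_accessions=60, group_sizes=(24, 36), n_genes=120, n_target_genes=20,
        n_network_genes=12, n_snps=60, n_causal_snps=8, n_stop_gain_causal=3,
        n_diff_edges=2, n_noncoding_genes=4, n_organellar_genes=4,
        n_decoy_sites=15, seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def default_bundle():
    return generate_dataset(GeneratorConfig(seed=11))


def make_toy_gene(strand: str = "+", cds: str = "ATGGATCTTCAGTAA",
                  chrom: str = "ChrT", pad: int = 30):
    """A single-gene annotation whose CDS sequence is ``cds`` (read 5'->3' on
    the coding strand). Returns (annotation, gene)."""
    rng = np.random.default_rng(7)
    left = "".join(rng.choice(list("ACGT"), pad))
    right = "".join(rng.choice(list("ACGT"), pad))
    if strand == "+":
        genomic_cds = cds
    else:
        genomic_cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seq = left + genomic_cds + right
    start, end = pad, pad + len(cds)
    gene = Gene("TOY1", chrom, start - 10, end + 10, strand,
                "protein_coding", "nuclear", ((start, end, 0),))
    return GenomeAnnotation([gene], {chrom: seq}), gene
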