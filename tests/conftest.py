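"""Shared fixtures: tiny gene models, introns, and an in-memory genome."""

import numpy as np
import pytest

from sisrna.annotation import GeneModel, IntronRecord, build_unique_introns


@pytest.fixture
def rng():
    return np.random.default_rng(20230807)


@pytest.fixture
def two_isoform_gene():
    """Gene with T1 exons [0,100),[200,300) and T2 exons [0,100),[250,300)."""
    return GeneModel(
        gene_id="gA",
        biotype="protein_coding",
        chrom="chr1",
        strand="+",
        transcripts=(((0, 100), (200, 300)), ((0, 100), (250, 300))),
    )


def make_intron(
    intron_id="i1",
    chrom="chr1",
    strand="+",
    start=100,
    end=200,
    kept_blocks=None,
    gene_id="g",
):
    if kept_blocks is None:
        kept_blocks = ((start, end),)
    return IntronRecord(intron_id, chrom, strand, start, end, tuple(kept_blocks), gene_id)


@pytest.fixture
def intron_plus():
    return make_intron("ip", strand="+", start=100, end=200)


@pytest.fixture
def intron_minus():
    return make_intron("im", strand="-", start=100, end=200)


def random_gene_models(rng, n_genes=30, chrom="chr1"):
    """Random multi-isoform gene models laid out along one chromosome."""
    genes = []
    cursor = 0
    for gi in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 6))
        exons = []
        pos = cursor + int(rng.integers(10, 50))
        for _ in range(n_exons):
            length = int(rng.integers(20, 120))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(30, 400))
        transcripts = [tuple(exons)]
        if rng.random() < 0.5:  # alternative isoform: drop/extend an exon
            alt = list(exons)
            k = int(rng.integers(0, len(alt)))
            s, e = alt[k]
            alt[k] = (s, e + int(rng.integers(1, 30)))
            transcripts.append(tuple(sorted(alt)))
        genes.append(
            GeneModel(
                gene_id=f"g{gi:03d}",
                biotype="protein_coding",
                chrom=chrom,
                strand=strand,
                transcripts=tuple(transcripts),
            )
        )
        cursor = pos
    return genes


@pytest.fixture
def random_introns(rng):
    return build_unique_introns(random_gene_models(rng))
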