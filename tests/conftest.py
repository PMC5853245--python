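import numpy as np
import pytest

from woxnet import GeneModel, GenomeSequences, SimConfig, build_synthetic_genome
from woxnet.motif_scan import DEFAULT_PATTERNS, reverse_complement
from woxnet.synthetic_data import _BASES, _sanitize

# literal -> (orientation, owning pattern), the four strings a forward-strand
# window can equal
MOTIF_LITERALS = {
    "TTAATGG": ("forward", "TTAATGG"),
    "TTAATGC": ("forward", "TTAATGC"),
    "CCATTAA": ("reverse", "TTAATGG"),
    "GCATTAA": ("reverse", "TTAATGC"),
}


def brute_force_motif_sites(seq: str) -> list[tuple[int, str, str]]:
    """Independent oracle: test every window against all four literal strings."""
    out = []
    for i in range(len(seq) - 6):
        window = seq[i : i + 7]
        if window in MOTIF_LITERALS:
            orientation, pattern = MOTIF_LITERALS[window]
            out.append((i, orientation, pattern))
    return out


def random_clean_seq(rng: np.random.Generator, n: int) -> str:
    """Random sequence with all spontaneous motif occurrences destroyed."""
    arr = _BASES[rng.integers(0, 4, size=n)].copy()
    _sanitize(arr, rng, set(), DEFAULT_PATTERNS)
    return "".join(arr)


def flip_genome(genome: GenomeSequences, genes: list[GeneModel]):
    """Reverse-complement every contig and mirror all gene coordinates/strands."""
    lengths = genome.lengths
    flipped_contigs = {c: reverse_complement(s) for c, s in genome.contigs.items()}

    def flip_iv(iv, L):
        s, e = iv
        return (L - e, L - s)

    flipped_genes = []
    for g in genes:
        L = lengths[g.contig]
        flipped_genes.append(
            GeneModel(
                gene_id=g.gene_id,
                contig=g.contig,
                strand="-" if g.strand == "+" else "+",
                span_start=L - g.span_end,
                span_end=L - g.span_start,
                exons=[flip_iv(iv, L) for iv in g.exons],
                utr5=[flip_iv(iv, L) for iv in g.utr5],
                utr3=[flip_iv(iv, L) for iv in g.utr3],
                cds=[flip_iv(iv, L) for iv in g.cds],
            )
        )
    return GenomeSequences(flipped_contigs), flipped_genes


@pytest.fixture(scope="session")
def sim():
    """One deterministic synthetic genome shared by the read-only tests."""
    cfg = SimConfig(seed=101)
    genome, genes, truth = build_synthetic_genome(cfg)
    return cfg, genome, genes, truth


@pytest.fixture()
def plus_gene():
    # two exons, UTRs at the transcript ends, one intron [5400, 5700)
    return GeneModel(
        gene_id="gplus",
        contig="chrT",
        strand="+",
        span_start=5000,
        span_end=6200,
        exons=[(5000, 5400), (5700, 6200)],
        utr5=[(5000, 5100)],
        utr3=[(6050, 6200)],
        cds=[(5100, 5400), (5700, 6050)],
    )


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(7)
    return GenomeSequences({"chrT": random_clean_seq(rng, 12000)})
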