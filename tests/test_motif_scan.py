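import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from woxnet import (
    GeneModel,
    GenomeSequences,
    MotifSpec,
    classify_position,
    find_motif_sites,
    flag_motif_genes,
    reverse_complement,
    scan_gene,
    scan_genes,
    summarize_distribution,
)
from woxnet.motif_scan import CATEGORIES, MotifError, MotifHit

from conftest import brute_force_motif_sites, flip_genome

dna = st.text(alphabet="ACGTN", max_size=60)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("TTAATGG", "CCATTAA"), ("TTAATGC", "GCATTAA"), ("N", "N"), ("", "")]
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(derandomize=True, max_examples=100)
    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_non_nucleotides(self):
        with pytest.raises(MotifError):
            reverse_complement("ACGU")


class TestFindMotifSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("TTAATGG", [(0, "forward", "TTAATGG")]),
            ("CCATTAA", [(0, "reverse", "TTAATGG")]),
            ("GCATTAA", [(0, "reverse", "TTAATGC")]),
            ("AAAAAAAA", []),
            ("", []),
        ],
    )
    def test_examples(self, seq, expected):
        assert find_motif_sites(seq, MotifSpec()) == expected

    def test_overlapping_occurrences_all_reported(self):
        # TTAATGC at 0 and CCATTAA overlap is impossible for these literals,
        # but adjacent/overlapping same-orientation matches must all appear
        seq = "TTAATGGTTAATGG"
        assert [h[0] for h in find_motif_sites(seq, MotifSpec())] == [0, 7]

    def test_forward_only_when_both_strands_disabled(self):
        spec = MotifSpec(search_both_strands=False)
        assert find_motif_sites("CCATTAA", spec) == []
        assert find_motif_sites("TTAATGG", spec) == [(0, "forward", "TTAATGG")]

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(bases[rng.integers(0, 4, size=3000)])
            assert find_motif_sites(seq, MotifSpec()) == sorted(brute_force_motif_sites(seq))

    def test_spec_validation(self):
        with pytest.raises(MotifError):
            MotifSpec(patterns=())
        with pytest.raises(MotifError):
            MotifSpec(patterns=("ACG",))
        with pytest.raises(MotifError):
            MotifSpec(patterns=("ACGU",))


class TestClassifyPosition:
    def test_promoter_window(self, plus_gene):
        assert classify_position(4500, plus_gene, 1000) == "promoter"
        assert classify_position(4999, plus_gene, 1000) == "promoter"

    def test_intron_gap(self, plus_gene):
        assert classify_position(5500, plus_gene, 1000) == "intron"

    def test_utr_and_cds_split_of_exons(self, plus_gene):
        assert classify_position(5050, plus_gene, 1000) == "utr5"
        assert classify_position(5200, plus_gene, 1000) == "exon"
        assert classify_position(6100, plus_gene, 1000) == "utr3"

    def test_outside_promoter_and_body_is_error(self, plus_gene):
        with pytest.raises(MotifError):
            classify_position(3999, plus_gene, 1000)
        with pytest.raises(MotifError):
            classify_position(6200, plus_gene, 1000)

    def test_per_base_oracle_partition(self, sim):
        """Every base of promoter + gene body receives exactly one category,
        and that category agrees with exhaustive interval membership."""
        cfg, genome, genes, _ = sim
        for gene in genes[:10]:
            clen = genome.lengths[gene.contig]
            if gene.strand == "+":
                positions = range(max(0, gene.span_start - cfg.promoter_len), gene.span_end)
                prom = (max(0, gene.span_start - cfg.promoter_len), gene.span_start)
            else:
                positions = range(gene.span_start, min(clen, gene.span_end + cfg.promoter_len))
                prom = (gene.span_end, min(clen, gene.span_end + cfg.promoter_len))
            def inside(pos, ivs):
                return any(s <= pos < e for s, e in ivs)

            for pos in positions:
                in_span = gene.span_start <= pos < gene.span_end
                in_exon = inside(pos, gene.exons)
                members = [
                    c
                    for c, hit in [
                        ("promoter", prom[0] <= pos < prom[1]),
                        ("utr5", inside(pos, gene.utr5)),
                        ("utr3", inside(pos, gene.utr3)),
                        ("exon", in_exon and not inside(pos, gene.utr5 + gene.utr3)),
                        ("intron", in_span and not in_exon),
                    ]
                    if hit
                ]
                assert len(members) == 1
                assert classify_position(pos, gene, cfg.promoter_len, clen) == members[0]


def plant(seq: str, pos: int, literal: str) -> str:
    return seq[:pos] + literal + seq[pos + len(literal) :]


class TestScanGene:
    def test_single_promoter_site(self, toy_genome, plus_gene):
        seq = plant(toy_genome.contigs["chrT"], 4500, "TTAATGG")
        genome = GenomeSequences({"chrT": seq})
        hits = scan_gene(plus_gene, genome)
        assert len(hits) == 1
        (h,) = hits
        assert (h.category, h.genomic_start, h.offset_from_tss) == ("promoter", 4500, -500)

    def test_clean_background_yields_no_hits(self, toy_genome, plus_gene):
        assert scan_gene(plus_gene, toy_genome) == []

    def test_minus_strand_mirror_gene_gives_identical_relative_hits(self, toy_genome):
        """A site planted in gene orientation produces the same gene-relative
        hit on a plus-strand gene and on its minus-strand mirror."""
        base = toy_genome.contigs["chrT"]
        plus = GeneModel("g", "chrT", "+", 3000, 4500, exons=[(3000, 4500)])
        seq_plus = plant(base, 3300, "TTAATGG")
        hits_plus = scan_gene(plus, GenomeSequences({"chrT": seq_plus}))

        L = len(base)
        minus = GeneModel(
            "g", "chrT", "-", L - 4500, L - 3000, exons=[(L - 4500, L - 3000)]
        )
        hits_minus = scan_gene(minus, GenomeSequences({"chrT": reverse_complement(seq_plus)}))
        key = lambda hs: [(h.offset_from_tss, h.category, h.matched_pattern) for h in hs]
        assert key(hits_plus) == key(hits_minus) != []

    def test_strand_invariance_of_full_table(self, sim):
        _, genome, genes, _ = sim
        fwd = scan_genes(genes, genome)
        flipped_genome, flipped_genes = flip_genome(genome, genes)
        rev = scan_genes(flipped_genes, flipped_genome)
        key = lambda hs: sorted((h.gene_id, h.offset_from_tss, h.category) for h in hs)
        assert key(fwd) == key(rev)


class TestFlagAndSummarize:
    def hit(self, gene_id, category):
        return MotifHit(gene_id, "c", 0, "forward", "TTAATGG", category, 10)

    def test_flag_is_set_valued(self):
        hits = [self.hit("a", "intron")] * 3 + [self.hit("b", "promoter")]
        assert flag_motif_genes(hits) == {"a", "b"}
        assert flag_motif_genes([]) == set()

    def test_flag_equals_per_gene_rescan(self, sim):
        _, genome, genes, _ = sim
        flagged = flag_motif_genes(scan_genes(genes, genome))
        assert flagged == {g.gene_id for g in genes if scan_gene(g, genome)}

    def test_distribution_arithmetic(self):
        hits = (
            [self.hit("g", "intron")] * 9
            + [self.hit("g", "promoter")] * 6
            + [self.hit("g", "exon")] * 3
            + [self.hit("g", "utr3")] * 2
        )
        dist = summarize_distribution(hits)
        assert dist.counts == {"intron": 9, "promoter": 6, "exon": 3, "utr3": 2, "utr5": 0}
        assert dist.percentages == {
            "intron": 45.0,
            "promoter": 30.0,
            "exon": 15.0,
            "utr3": 10.0,
            "utr5": 0.0,
        }

    def test_single_category_is_100_percent(self):
        dist = summarize_distribution([self.hit("g", "utr5")] * 4)
        assert dist.percentages["utr5"] == 100.0
        assert sum(dist.percentages.values()) == 100.0

    def test_empty_hit_list_is_error(self):
        with pytest.raises(MotifError):
            summarize_distribution([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(CATEGORIES), min_size=1, max_size=200))
    def test_percentages_sum_to_100(self, cats):
        dist = summarize_distribution([self.hit("g", c) for c in cats])
        assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=0.1)
        assert sum(dist.counts.values()) == len(cats)
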