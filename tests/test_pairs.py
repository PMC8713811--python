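import random

import pytest

from wcat.pairs import (
    GeneModel,
    find_head_to_head_pairs,
    match_exon_template,
    read_gff3,
    write_gff3,
)
from wcat.simulate import CLASS_II_TYPE_EXONS, SimConfig, make_locus_gff


def _gene(gene_id, strand, start, exon_lengths, contig="c1", intron=300):
    exons = []
    pos = start
    order = exon_lengths if strand == "+" else tuple(reversed(exon_lengths))
    for L in order:
        exons.append((pos, pos + L))
        pos += L + intron
    return GeneModel(gene_id, contig, strand, exons)


class TestExonTemplates:
    def test_class_ii_type_gene_matches(self):
        gene = _gene("wa", "+", 100, CLASS_II_TYPE_EXONS)
        matched, reasons = match_exon_template(gene, "CLASS_II_TYPE")
        assert matched, reasons

    def test_class_i_gene_matches_class_i_template(self):
        gene = _gene("hla", "+", 100, (270, 276, 276, 120, 90))
        matched, reasons = match_exon_template(gene, "CLASS_I")
        assert matched, reasons

    def test_minus_strand_gene_is_read_in_transcription_order(self):
        gene = _gene("wb", "-", 100, CLASS_II_TYPE_EXONS)
        matched, reasons = match_exon_template(gene, "CLASS_II_TYPE")
        assert matched, reasons

    def test_single_exon_gene_fails_with_reason(self):
        gene = GeneModel("tiny", "c1", "+", [(0, 500)])
        matched, reasons = match_exon_template(gene, "CLASS_II_TYPE")
        assert not matched
        assert "too few exons" in reasons[0]

    def test_wrong_exon_length_fails_with_reason(self):
        gene = _gene("odd", "+", 100, (50, 276, 120))
        matched, reasons = match_exon_template(gene, "CLASS_II_TYPE")
        assert not matched
        assert any("distal exon" in r for r in reasons)


class TestHeadToHeadPairs:
    def test_facing_pair_within_distance_is_called(self):
        minus = _gene("b", "-", 1_000, CLASS_II_TYPE_EXONS)
        plus = _gene("a", "+", minus.end + 2_000, CLASS_II_TYPE_EXONS)
        pairs = find_head_to_head_pairs([minus, plus])
        assert len(pairs) == 1
        assert pairs[0].genes == ("b", "a")
        assert pairs[0].distance == 2_000

    def test_same_strand_neighbours_are_not_paired(self):
        g1 = _gene("x", "+", 1_000, CLASS_II_TYPE_EXONS)
        g2 = _gene("y", "+", g1.end + 2_000, CLASS_II_TYPE_EXONS)
        assert find_head_to_head_pairs([g1, g2]) == []

    def test_tail_to_tail_orientation_is_not_paired(self):
        g1 = _gene("x", "+", 1_000, CLASS_II_TYPE_EXONS)
        g2 = _gene("y", "-", g1.end + 2_000, CLASS_II_TYPE_EXONS)
        assert find_head_to_head_pairs([g1, g2]) == []

    def test_distance_cap_applies(self):
        minus = _gene("b", "-", 1_000, CLASS_II_TYPE_EXONS)
        plus = _gene("a", "+", minus.end + 25_000, CLASS_II_TYPE_EXONS)
        assert find_head_to_head_pairs([minus, plus], max_distance=20_000) == []
        assert len(find_head_to_head_pairs([minus, plus], max_distance=30_000)) == 1

    def test_result_is_invariant_to_input_order(self):
        genes, _ = make_locus_gff(3, 5, SimConfig(seed=1))
        pairs1 = find_head_to_head_pairs(genes)
        rng = random.Random(0)
        for _ in range(5):
            shuffled = genes[:]
            rng.shuffle(shuffled)
            assert find_head_to_head_pairs(shuffled) == pairs1

    def test_each_gene_joins_at_most_one_pair(self):
        # minus gene with two plus genes downstream: only nearest pairs
        minus = _gene("m", "-", 1_000, CLASS_II_TYPE_EXONS)
        plus1 = _gene("p1", "+", minus.end + 1_000, CLASS_II_TYPE_EXONS)
        plus2 = _gene("p2", "+", plus1.end + 1_000, CLASS_II_TYPE_EXONS)
        pairs = find_head_to_head_pairs([minus, plus1, plus2])
        assert [p.genes for p in pairs] == [("m", "p1")]

    def test_mirroring_the_contig_mirrors_the_pairs(self):
        genes, _ = make_locus_gff(2, 3, SimConfig(seed=2))
        total = max(g.end for g in genes) + 1_000
        mirrored = [
            GeneModel(g.gene_id, g.contig, "-" if g.strand == "+" else "+",
                      [(total - e, total - s) for s, e in g.exons])
            for g in genes
        ]
        original = {frozenset(p.genes) for p in find_head_to_head_pairs(genes)}
        flipped = {frozenset(p.genes) for p in find_head_to_head_pairs(mirrored)}
        assert original == flipped

    def test_three_pair_cluster_is_fully_recovered(self):
        genes, truth = make_locus_gff(3, 0, SimConfig(seed=4))
        pairs = find_head_to_head_pairs(genes)
        assert {p.genes for p in pairs} == {tuple(t) for t in truth["pairs"]}


class TestGff3RoundTrip:
    def test_write_then_read_preserves_gene_models(self, tmp_path):
        genes, _ = make_locus_gff(2, 2, SimConfig(seed=5))
        path = tmp_path / "locus.gff3"
        write_gff3(genes, path)
        loaded = read_gff3(path)
        assert {g.gene_id for g in loaded} == {g.gene_id for g in genes}
        by_id = {g.gene_id: g for g in loaded}
        for g in genes:
            assert by_id[g.gene_id].exons == g.exons
            assert by_id[g.gene_id].strand == g.strand
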