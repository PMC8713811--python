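import random

import pytest

from wcat.mapper import (
    MAPPING_THRESHOLD,
    MappingError,
    NotMhcLikeError,
    assemble,
    find_tm_segment,
    map_to_frame,
    segment_chain,
)
from wcat.simulate import SimConfig, make_chain

from ._oracles import gotoh_global_score


class TestMapToFrame:
    def test_self_mapping_is_identity_with_score_one(self, schema):
        frame = schema.frame("IG_C1")
        hit = map_to_frame(frame.consensus, frame)
        assert hit.score == pytest.approx(1.0)
        assert hit.position_map == {c: c - 1 for c in frame.columns}

    def test_consensus_read_back_through_identity_map(self, schema):
        frame = schema.frame("DISTAL_A1TYPE")
        hit = map_to_frame(frame.consensus, frame)
        rebuilt = "".join(hit.residue_at(frame.consensus, c) for c in frame.columns)
        assert rebuilt == frame.consensus

    def test_single_insertion_shifts_downstream_indices_only(self, schema):
        frame = schema.frame("IG_C1")
        mid = frame.length // 2
        inserted = frame.consensus[:mid] + "W" + frame.consensus[mid:]
        hit = map_to_frame(inserted, frame)
        for col in frame.columns:
            expected = col - 1 if col - 1 < mid else col
            assert hit.position_map[col] == expected

    @pytest.mark.parametrize("n", [8, 15, 30])
    def test_alignment_score_matches_gotoh_oracle(self, schema, n):
        """Optimal affine-gap score agrees with a longhand three-matrix DP."""
        from wcat.mapper import _GLOBAL

        rng = random.Random(n)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(rng.choice(aa) for _ in range(n))
            b = "".join(rng.choice(aa) for _ in range(rng.randint(max(3, n - 4), n + 4)))
            assert _GLOBAL.score(a, b) == pytest.approx(gotoh_global_score(a, b))

    def test_shuffled_consensus_scores_below_threshold(self, schema):
        frame = schema.frame("IG_C1")
        rng = random.Random(123)
        above = 0
        for _ in range(300):
            shuffled = list(frame.consensus)
            rng.shuffle(shuffled)
            hit = map_to_frame("".join(shuffled), frame)
            above += hit.score >= MAPPING_THRESHOLD
        assert above / 300 < 0.01

    def test_score_symmetry_under_self_comparison(self, schema):
        for frame in schema.frames.values():
            assert map_to_frame(frame.consensus, frame).score == pytest.approx(1.0)

    def test_score_non_increasing_with_mutation_count(self, schema):
        frame = schema.frame("IG_C1")
        rng = random.Random(5)
        seq = list(frame.consensus)
        previous = 1.0
        positions = rng.sample(range(frame.length), 40)
        for k, pos in enumerate(positions):
            alternatives = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != seq[pos]]
            seq[pos] = rng.choice(alternatives)
            if (k + 1) % 10 == 0:
                score = map_to_frame("".join(seq), frame).score
                assert score <= previous + 1e-9
                previous = score

    def test_too_short_sequence_is_no_confident_mapping(self, schema):
        with pytest.raises(MappingError, match="no confident mapping"):
            map_to_frame("ACDEFGHIKL", schema.frame("IG_C1"))


class TestSegmentChain:
    def test_class_i_heavy_chain_has_three_extracellular_domains(self, schema, clean_config):
        seq, _ = make_chain("I_HEAVY", clean_config)
        arch = segment_chain(seq, schema, chain_id="h")
        assert arch.extracellular_domain_count == 3
        assert arch.cptmcy_count == 1
        assert [h.frame for h in arch.hits] == ["DISTAL_A1TYPE", "DISTAL_A2TYPE", "IG_C1"]

    def test_b2m_like_chain_is_single_ig_domain_without_tm(self, schema, clean_config):
        seq, _ = make_chain("B2M", clean_config)
        arch = segment_chain(seq, schema, chain_id="b2m")
        assert arch.extracellular_domain_count == 1
        assert arch.cptmcy_count == 0
        assert arch.hits[0].frame == "IG_C1"

    @pytest.mark.parametrize("label", ["IIA", "IIB", "WA", "WB"])
    def test_two_domain_chains(self, schema, clean_config, label):
        seq, _ = make_chain(label, clean_config)
        arch = segment_chain(seq, schema, chain_id=label)
        assert arch.extracellular_domain_count == 2
        assert arch.cptmcy_count == 1

    def test_short_peptide_is_a_precondition_error(self, schema):
        with pytest.raises(ValueError, match="too short"):
            segment_chain("ACDEFGHIKLMNPQRSTVWY", schema)

    def test_random_sequence_is_not_mhc_like(self, schema):
        rng = random.Random(77)
        seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(300))
        with pytest.raises(NotMhcLikeError):
            segment_chain(seq, schema)

    def test_assembled_molecule_counts(self, schema, clean_config):
        heavy, _ = make_chain("I_HEAVY", clean_config)
        b2m, _ = make_chain("B2M", clean_config)
        class_i = assemble(segment_chain(heavy, schema), segment_chain(b2m, schema))
        assert class_i.cptmcy_count == 1
        assert class_i.extracellular_domain_count == 4

        wa, _ = make_chain("WA", clean_config)
        wb, _ = make_chain("WB", clean_config)
        class_ii_type = assemble(segment_chain(wa, schema), segment_chain(wb, schema))
        assert class_ii_type.cptmcy_count == 2
        assert class_ii_type.extracellular_domain_count == 4


class TestTmScan:
    def test_hydrophobic_stretch_is_found(self):
        seq = "MKT" + "E" * 30 + "LLLVVIAILFFAMIVLLGAIV" + "RKSSNE"
        interval = find_tm_segment(seq)
        assert interval is not None
        lo, hi = interval
        core_mid = 33 + 21 // 2  # centre of the hydrophobic stretch
        assert lo <= core_mid <= hi
        assert hi <= len(seq)
        # the called segment is mostly the hydrophobic stretch, not the acidic run
        assert lo >= 25

    def test_hydrophilic_sequence_has_no_tm(self):
        assert find_tm_segment("KRDEQN" * 20) is None
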