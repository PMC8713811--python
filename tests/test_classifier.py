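import itertools

import numpy as np
import pytest

from wcat.classifier import (
    classify_chain,
    classify_sequence,
    evaluate_interfaces,
    score_domain,
)
from wcat.frames import (
    PositionFrame,
    ResidueSignature,
    SignatureSchema,
)
from wcat.mapper import DomainHit, segment_chain
from wcat.simulate import LAYOUTS, SimConfig, make_chain, make_chain_set


def _identity_hit(frame, sequence):
    return DomainHit(
        chain_id="toy", start=0, end=len(sequence), frame=frame.name, score=1.0,
        position_map={c: c - frame.numbering_origin for c in frame.columns},
    )


def _toy_schema():
    """3-column Ig frame with competing classes (WA and IIA symmetric)."""
    frame = PositionFrame(name="IG_C1", length=3, consensus="ACD")
    sigs = [
        ResidueSignature("IG_C1", 1, frozenset("A"), "B2M", "CORE", 2.0),
        ResidueSignature("IG_C1", 2, frozenset("C"), "B2M", "CORE", 1.0),
        ResidueSignature("IG_C1", 2, frozenset("C"), "WA", "CORE", 1.0),
        ResidueSignature("IG_C1", 3, frozenset("DE"), "WA", "CORE", 2.0),
        ResidueSignature("IG_C1", 2, frozenset("C"), "IIA", "CORE", 1.0),
        ResidueSignature("IG_C1", 3, frozenset("DE"), "IIA", "CORE", 2.0),
    ]
    schema = SignatureSchema(version="toy", frames={"IG_C1": frame}, signatures=sigs)
    schema.validate()
    return schema, frame


class TestScoreDomain:
    def test_planted_b2m_ig_domain_scores_one(self, schema, clean_config):
        seq, _ = make_chain("B2M", clean_config)
        arch = segment_chain(seq, schema)
        scores = score_domain(arch.hits[0], seq, schema)
        matched, readable, _ = scores["B2M"]
        assert readable > 0
        assert matched == readable

    def test_all_gapped_signature_columns_flag_zero_coverage(self, schema):
        frame = schema.frame("IG_C1")
        hit = DomainHit("x", 0, frame.length, "IG_C1", 1.0,
                        position_map={c: None for c in frame.columns})
        scores = score_domain(hit, frame.consensus, schema)
        assert all(readable == 0 for _, readable, _ in scores.values())

    def test_toy_frame_scores_match_exhaustive_enumeration(self):
        schema, frame = _toy_schema()
        weights = {
            "B2M": {1: (frozenset("A"), 2.0), 2: (frozenset("C"), 1.0)},
            "WA": {2: (frozenset("C"), 1.0), 3: (frozenset("DE"), 2.0)},
        }
        for combo in itertools.product("ACDE", repeat=3):
            seq = "".join(combo)
            hit = _identity_hit(frame, seq)
            scores = score_domain(hit, seq, schema)
            for cls, table in weights.items():
                expected_num = sum(w for pos, (allowed, w) in table.items()
                                   if seq[pos - 1] in allowed)
                expected_den = sum(w for _, w in table.values())
                assert scores[cls][0] == pytest.approx(expected_num)
                assert scores[cls][1] == pytest.approx(expected_den)


class TestClassifyChain:
    @pytest.mark.parametrize("label", sorted(LAYOUTS))
    def test_noise_free_chains_recover_their_label(self, schema, clean_config, label):
        seq, truth = make_chain(label, clean_config)
        call = classify_sequence(seq, schema, chain_id=label)
        assert call.label == truth["label"]
        assert call.scores[label] == pytest.approx(1.0)

    def test_constructed_tie_is_unknown_with_margin_zero(self):
        schema, frame = _toy_schema()
        seq = "ACD"  # matches all WA/IIA signatures, which are symmetric
        hit = _identity_hit(frame, seq)
        from wcat.mapper import ChainArchitecture

        arch = ChainArchitecture(chain_id="tie", hits=[hit, hit])  # 2 domains: II gate
        call = classify_chain(arch, seq, schema)
        assert call.scores["WA"] == pytest.approx(call.scores["IIA"]) == 1.0
        assert call.margin == pytest.approx(0.0)
        assert call.label == "UNKNOWN"

    def test_unmappable_chain_reports_not_mhc_like(self, schema):
        call = classify_sequence("KRDEQNSTH" * 30, schema, chain_id="junk")
        assert call.label == "UNKNOWN"
        assert "Ig C1" in call.note

    def test_signature_free_chains_are_mostly_unknown(self, schema):
        """Permutation null: random residues at every diagnostic position."""
        cfg = SimConfig(seed=31, mu=0.0, count_per_class=20)
        records = make_chain_set(cfg, randomize_signatures=True)
        labels = [
            classify_sequence(seq, schema, chain_id=name).label
            for name, (seq, _) in records.items()
        ]
        unknown_rate = labels.count("UNKNOWN") / len(labels)
        assert unknown_rate >= 0.95

    def test_accuracy_non_increasing_in_mutation_rate(self, schema):
        rates = (0.0, 0.05, 0.1)
        accs = []
        for mu in rates:
            cfg = SimConfig(seed=13, mu=mu, count_per_class=15)
            records = make_chain_set(cfg)
            hits = [
                classify_sequence(seq, schema, chain_id=name).label == truth["label"]
                for name, (seq, truth) in records.items()
            ]
            accs.append(np.mean(hits))
        n = 15 * len(LAYOUTS)
        for lo, hi in zip(accs[1:], accs[:-1]):
            se = np.sqrt(max(hi * (1 - hi), 0.25 / n) / n)
            assert lo <= hi + 2 * se


class TestInterfaces:
    def test_report_always_has_exactly_three_interfaces(self, schema, clean_config):
        wa, _ = make_chain("WA", clean_config)
        wb, _ = make_chain("WB", clean_config)
        report = evaluate_interfaces(
            classify_sequence(wa, schema, "wa"), classify_sequence(wb, schema, "wb"), schema
        )
        assert set(report.interfaces) == {"A1A2_B2M", "A1A2_A3", "A3_B2M"}

    def test_wa_wb_pair_is_class_i_type_at_all_three_interfaces(self, schema, clean_config):
        wa, _ = make_chain("WA", clean_config)
        wb, _ = make_chain("WB", clean_config)
        report = evaluate_interfaces(
            classify_sequence(wa, schema, "wa"), classify_sequence(wb, schema, "wb"), schema
        )
        assert report.verdicts() == {
            "A1A2_B2M": "CLASS_I_TYPE",
            "A1A2_A3": "CLASS_I_TYPE",
            "A3_B2M": "CLASS_I_TYPE",
        }

    def test_class_i_molecule_is_class_i_type(self, schema, clean_config):
        b2m, _ = make_chain("B2M", clean_config)
        heavy, _ = make_chain("I_HEAVY", clean_config)
        report = evaluate_interfaces(
            classify_sequence(b2m, schema, "b2m"), classify_sequence(heavy, schema, "h"), schema
        )
        assert set(report.verdicts().values()) == {"CLASS_I_TYPE"}

    def test_class_ii_pair_shows_the_diagnostic_tryptophan(self, schema, clean_config):
        iia, _ = make_chain("IIA", clean_config)
        iib, _ = make_chain("IIB", clean_config)
        report = evaluate_interfaces(
            classify_sequence(iia, schema, "a"), classify_sequence(iib, schema, "b"), schema
        )
        assert report.verdicts()["A1A2_A3"] == "CLASS_II_TYPE"
        assert report.verdicts()["A1A2_B2M"] != "CLASS_I_TYPE"

    def test_gapped_position_61_makes_interface_ambiguous(self, schema, clean_config):
        wa, _ = make_chain("WA", clean_config)
        wb, _ = make_chain("WB", clean_config)
        alpha = classify_sequence(wa, schema, "wa")
        beta = classify_sequence(wb, schema, "wb")
        for hit in beta.architecture.ig_hits:
            hit.position_map[61] = None
        report = evaluate_interfaces(alpha, beta, schema)
        assert report.verdicts()["A1A2_A3"] == "AMBIGUOUS"
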