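import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbdrank.kg_core import ValidationError
from lbdrank.ner import (
    EntityMention,
    assemble_triples,
    compile_dictionary,
    extract_entities,
    prepare_relation_inputs,
    type_pair_predictor,
)
from lbdrank.synthetic import generate_corpus


@pytest.fixture
def compound_dict():
    return compile_dictionary(
        [
            ("3,5-dicaffeoylquinic acid", "3,5_dicaffeoylquinic_acid", "compound"),
            ("4,5-dicaffeoylquinic acid", "4,5_dicaffeoylquinic_acid", "compound"),
            ("caffeic acid", "caffeic_acid", "compound"),
            ("caffeic acid ethyl ester", "caffeic_acid_ethyl_ester", "compound"),
            ("choline", "choline", "compound"),
        ],
        priority=1,
    )


@pytest.fixture
def phenotype_dict():
    return compile_dictionary(
        [("type 2 diabetes", "type_2_diabetes", "phenotype"), ("glucose", "glucose", "compound")]
    )


class TestCompileDictionary:
    def test_terms_are_normalized(self, compound_dict):
        assert "3,5_dicaffeoylquinic_acid" in compound_dict.entries

    def test_duplicate_normalized_terms_first_wins(self, caplog):
        d = compile_dictionary(
            [("Caffeic Acid", "first", "compound"), ("caffeic-acid", "second", "compound")]
        )
        assert d.entries["caffeic_acid"][0] == "first"

    def test_unknown_entity_type_rejected(self):
        with pytest.raises(ValidationError):
            compile_dictionary([("x", "x", "disease")])

    def test_empty_entry_list_rejected(self):
        with pytest.raises(ValidationError):
            compile_dictionary([])


class TestExtractEntities:
    def test_finds_both_acids_in_herbal_sentence(self, compound_dict):
        sentence = (
            "A. fragrans is a traditional Chinese herbal that contains components "
            "like 3,5-dicaffeoylquinic acid and 4,5-dicaffeoylquinic acid."
        )
        mentions = extract_entities(sentence, [compound_dict])
        assert [m.node_id for m in mentions] == [
            "3,5_dicaffeoylquinic_acid",
            "4,5_dicaffeoylquinic_acid",
        ]

    def test_longest_match_wins_over_substring_term(self, compound_dict):
        mentions = extract_entities(
            "the effect of caffeic acid ethyl ester was notable", [compound_dict]
        )
        assert [m.node_id for m in mentions] == ["caffeic_acid_ethyl_ester"]

    def test_no_dictionary_term_gives_empty_list(self, compound_dict):
        assert extract_entities("nothing relevant here", [compound_dict]) == []

    def test_matching_is_case_insensitive(self, compound_dict):
        (m,) = extract_entities("CHOLINE levels rose", [compound_dict])
        assert (m.node_id, m.start, m.end) == ("choline", 0, 7)

    def test_mentions_never_overlap_and_are_sorted(self, compound_dict, phenotype_dict):
        sentence = "caffeic acid ethyl ester and caffeic acid alter glucose in type 2 diabetes"
        mentions = extract_entities(sentence, [compound_dict, phenotype_dict])
        spans = [(m.start, m.end) for m in mentions]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in itertools.combinations(spans, 2):
            assert e1 <= s2 or e2 <= s1


class TestPrepareRelationInputs:
    def _mentions(self, sentence, dicts):
        return extract_entities(sentence, dicts, sentence_id="s1")

    def test_single_entity_sentence_is_skipped(self, compound_dict):
        text = "choline was measured"
        out = prepare_relation_inputs([("s1", text)], self._mentions(text, [compound_dict]))
        assert out == []

    def test_pair_masked_with_type_tokens(self, compound_dict, phenotype_dict):
        text = "choline treats type 2 diabetes"
        out = prepare_relation_inputs(
            [("s1", text)], self._mentions(text, [compound_dict, phenotype_dict])
        )
        (ri,) = out
        assert ri.masked_text == "@COMPOUND$ treats @PHENOTYPE$"
        assert (ri.head, ri.tail) == ("choline", "type_2_diabetes")

    def test_three_entities_give_all_three_pairs(self, compound_dict, phenotype_dict):
        text = "choline and caffeic acid modulate glucose"
        out = prepare_relation_inputs(
            [("s1", text)], self._mentions(text, [compound_dict, phenotype_dict])
        )
        assert len(out) == 3
        assert {frozenset((ri.head, ri.tail)) for ri in out} == {
            frozenset(p)
            for p in itertools.combinations(["choline", "caffeic_acid", "glucose"], 2)
        }

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=5))
    def test_pair_count_is_u_choose_2(self, u):
        terms = [f"term{i}" for i in range(u)]
        text = " and ".join(terms) if terms else "nothing"
        d = compile_dictionary(
            [(t, t, "compound") for t in terms] or [("placeholder", "placeholder", "compound")]
        )
        out = prepare_relation_inputs([("s1", text)], extract_entities(text, [d], "s1"))
        assert len(out) == (u * (u - 1)) // 2

    def test_out_of_bounds_span_is_a_validation_error(self):
        bad = EntityMention("s1", 5, 20, "x", "compound")
        with pytest.raises(ValidationError):
            prepare_relation_inputs([("s1", "short")], [bad])


class TestAssembleTriples:
    def _inputs(self, compound_dict, phenotype_dict, n=3):
        text = "choline treats type 2 diabetes"
        out = []
        for i in range(n):
            sid = f"s{i}"
            out.extend(
                prepare_relation_inputs(
                    [(sid, text)],
                    extract_entities(text, [compound_dict, phenotype_dict], sid),
                )
            )
        return out

    def test_threshold_filters_low_confidence(self, compound_dict, phenotype_dict):
        inputs = self._inputs(compound_dict, phenotype_dict, n=1)
        pred = type_pair_predictor({("compound", "phenotype"): "treats"}, confidence=0.4)
        assert assemble_triples(inputs, pred, threshold=0.5) == []
        (t,) = assemble_triples(inputs, pred, threshold=0.3)
        assert t.key == ("choline", "treats", "type_2_diabetes")

    def test_same_pair_across_sentences_merges_counts(self, compound_dict, phenotype_dict):
        inputs = self._inputs(compound_dict, phenotype_dict, n=3)
        (t,) = assemble_triples(inputs, type_pair_predictor(default="treats"))
        assert t.count == 3

    def test_out_of_vocabulary_prediction_rejected(self, compound_dict, phenotype_dict):
        inputs = self._inputs(compound_dict, phenotype_dict, n=1)
        with pytest.raises(ValidationError):
            assemble_triples(inputs, type_pair_predictor(default="cures"))


class TestCorpusRoundTrip:
    def test_planted_mentions_recovered_exactly(self):
        # no planted term is a substring of another, so extraction is exact
        d = compile_dictionary(
            [
                ("beta sitosterol", "beta_sitosterol", "compound"),
                ("quercetin", "quercetin", "compound"),
                ("type 2 diabetes", "type_2_diabetes", "phenotype"),
                ("abcc8", "abcc8", "gene"),
            ]
        )
        records, truth = generate_corpus(d, n_sentences=40, seed=7)
        found = []
        for rec in records:
            found.extend(extract_entities(rec["text"], [d], rec["sentence_id"]))
        assert set(found) == set(truth)  # precision = recall = 1.0
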