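"""Candidate pairs, dependency paths, masking, filtering, anti-positive list."""

import pytest

from ontorel.corpus import CandidatePair, Document, EntityMention, Sentence
from ontorel.preprocess import (
    NULL_SUPERSENSE,
    SUPERSENSE_INVENTORY,
    ChainParser,
    DependencyParse,
    LexiconSupersenseTagger,
    Token,
    UnmappableEntityError,
    build_anti_positive_list,
    build_instances,
    filter_negatives,
    generate_candidate_pairs,
    mask_entities,
    shortest_dependency_path,
    simple_tokenize,
)


def make_sentence(text, entity_words, gold=(), sid="s0", doc_id="d0"):
    """Entities given as surface words occurring once each in the text."""
    entities = []
    for k, w in enumerate(entity_words):
        start = text.index(w)
        entities.append(
            EntityMention(id=f"{sid}.e{k}", text=w, char_start=start, char_end=start + len(w) - 1)
        )
    sent = Sentence(id=sid, text=text, entities=entities)
    for (i, j, label) in gold:
        sent.gold_pairs.append(
            CandidatePair(
                e1=entities[i].id, e2=entities[j].id, label=label,
                provenance="gold", doc_id=doc_id, sentence_id=sid,
            )
        )
    return sent


class TestCandidatePairs:
    @pytest.mark.parametrize("n_entities", range(1, 7))
    def test_binomial_count(self, n_entities):
        words = [f"drug{c}" for c in "ABCDEF"[:n_entities]]
        sent = make_sentence("x " + " with ".join(words) + " y", words)
        pairs = generate_candidate_pairs(sent)
        assert len(pairs) == n_entities * (n_entities - 1) // 2

    def test_labels_joined_from_gold(self):
        words = ["drugA", "drugB", "drugC", "drugD"]
        sent = make_sentence(
            "x " + " with ".join(words) + " y", words,
            gold=[(0, 1, "effect"), (2, 3, "mechanism")],
        )
        pairs = generate_candidate_pairs(sent, doc_id="d0")
        assert len(pairs) == 6
        assert sum(p.is_positive for p in pairs) == 2
        labels = {p.key: p.label for p in pairs}
        assert labels[pairs[0].key] == "effect"


class TestShortestDependencyPath:
    def test_chain_parse_gives_contiguous_span(self):
        text = "t0 t1 drugA t3 t4 drugB t6"
        sent = make_sentence(text, ["drugA", "drugB"])
        parse = ChainParser().parse(text)
        path = shortest_dependency_path(parse, sent.entities[0], sent.entities[1])
        assert path == [2, 3, 4, 5]

    def test_shared_head_gives_three_token_path(self):
        tokens = [Token("drugA", 0, 4), Token("joins", 6, 10), Token("drugB", 12, 16)]
        parse = DependencyParse(tokens, heads=[1, 1, 1], labels=["dep", "root", "dep"])
        e1 = EntityMention(id="e0", text="drugA", char_start=0, char_end=4)
        e2 = EntityMention(id="e1", text="drugB", char_start=12, char_end=16)
        assert shortest_dependency_path(parse, e1, e2) == [0, 1, 2]

    def test_endpoints_and_bounds(self):
        text = "a b c drugA d drugB e f"
        sent = make_sentence(text, ["drugA", "drugB"])
        parse = ChainParser().parse(text)
        path = shortest_dependency_path(parse, sent.entities[0], sent.entities[1])
        assert 1 <= len(path) <= len(parse.tokens)
        assert path[0] == 3 and path[-1] == 5

    def test_unmappable_entity(self):
        parse = ChainParser().parse("alpha beta")
        ghost = EntityMention(id="g", text="zz", char_start=40, char_end=41)
        with pytest.raises(UnmappableEntityError):
            shortest_dependency_path(parse, ghost, ghost)


class TestMasking:
    def test_candidate_entities_masked(self):
        toks = ["Plenaxis", "Response", "monitored", "by", "measuring",
                "concentrations", "testosterone"]
        assert mask_entities(toks, [0, 6]) == [
            "entity", "Response", "monitored", "by", "measuring",
            "concentrations", "entity",
        ]

    def test_third_entity_on_path_masked_too(self):
        toks = ["drugA", "with", "drugC", "affects", "drugB"]
        assert mask_entities(toks, [0, 2, 4]) == [
            "entity", "with", "entity", "affects", "entity"
        ]

    def test_all_entity_path_stays_same_length(self):
        assert mask_entities(["a", "b"], [0, 1]) == ["entity", "entity"]


class TestSupersenseTagger:
    def test_alignment_and_inventory(self):
        tagger = LexiconSupersenseTagger({"monitored": "verb.perception"})
        toks = ["entity", "Response", "monitored", ",", "concentrations"]
        classes = tagger.tag(toks)
        assert len(classes) == len(toks)
        assert classes[0] == NULL_SUPERSENSE  # mask token
        assert classes[3] == NULL_SUPERSENSE  # punctuation
        assert classes[2] == "verb.perception"
        assert all(c in SUPERSENSE_INVENTORY or c == NULL_SUPERSENSE for c in classes)

    def test_41_category_inventory(self):
        assert len(SUPERSENSE_INVENTORY) == 41
        assert "noun.group" in SUPERSENSE_INVENTORY
        assert "verb.change" in SUPERSENSE_INVENTORY


def _rule3_fixture():
    """Sentence with five entities and hand-built governors."""
    text = "mixture contains drugA contains drugB holds drugC contains drugD sees drugE"
    words = text.split()
    tokens, pos = [], 0
    for w in words:
        start = text.index(w, pos)
        tokens.append(Token(w, start, start + len(w) - 1))
        pos = start + len(w)
    heads = [0, 0, 1, 0, 3, 0, 5, 0, 7, 0, 9]
    parse = DependencyParse(tokens, heads, ["root"] + ["dep"] * 10)
    sent = make_sentence(text, ["drugA", "drugB", "drugC", "drugD", "drugE"], sid="s3")
    return sent, parse


class TestNegativeFiltering:
    def test_twenty_pair_fixture(self):
        # sentence 1: same-text rule and punctuation-only rule
        text = "Aspirin , aspirin increases warfarin , heparin with ibuprofen"
        sent1 = make_sentence(text, ["Aspirin", "aspirin", "warfarin", "heparin", "ibuprofen"], sid="s1")
        pairs1 = generate_candidate_pairs(sent1)
        kept1, auto1 = filter_negatives(pairs1, sent1, ChainParser().parse(text))
        assert len(pairs1) == 10
        auto_sets = {frozenset((p.e1, p.e2)) for p in auto1}
        assert auto_sets == {
            frozenset(("s1.e0", "s1.e1")),  # Aspirin / aspirin (same text)
            frozenset(("s1.e2", "s1.e3")),  # warfarin , heparin (punctuation)
        }
        # "and"/"with" between entities are words, not punctuation: kept
        assert len(kept1) == 8

        # sentence 2: anti-positive governors, both entities required
        sent2, parse2 = _rule3_fixture()
        pairs2 = generate_candidate_pairs(sent2)
        kept2, auto2 = filter_negatives(pairs2, sent2, parse2, anti_positive_list=["contains"])
        assert len(pairs2) == 10
        auto_sets2 = {frozenset((p.e1, p.e2)) for p in auto2}
        assert auto_sets2 == {
            frozenset(("s3.e0", "s3.e1")),
            frozenset(("s3.e0", "s3.e3")),
            frozenset(("s3.e1", "s3.e3")),
        }
        assert len(kept2) == 7

        # partition property over all 20 pairs: nothing dropped silently
        assert len(kept1) + len(auto1) == 10
        assert len(kept2) + len(auto2) == 10
        for p in auto1 + auto2:
            assert p.provenance == "auto_negative"

    def test_intervening_words_keep_pair(self):
        text = "drugA increases the effect of drugB"
        sent = make_sentence(text, ["drugA", "drugB"])
        kept, auto = filter_negatives(
            generate_candidate_pairs(sent), sent, ChainParser().parse(text)
        )
        assert len(kept) == 1 and not auto


class TestAntiPositiveList:
    def _corpus(self):
        texts = [
            ("s0", "x contains drugA contains drugB", []),
            ("s1", "y contains drugC contains drugD", []),
            ("s2", "z contains drugE boosts drugF", []),
            ("s3", "w boosts drugG boosts drugH", [(0, 1, "effect")]),
        ]
        docs, parses = [], {}
        for sid, text, gold in texts:
            ents = [w for w in text.split() if w.startswith("drug")]
            sent = make_sentence(text, ents, gold=gold, sid=sid)
            parses[sid] = ChainParser().parse(text)
            docs.append(Document(id=sid, sentences=[sent]))
        return docs, parses

    def test_never_positive_governor_listed(self):
        docs, parses = self._corpus()
        # "contains" governs entities 5x, never over a positive pair
        assert build_anti_positive_list(docs, parses, min_count=3) == ["contains"]

    def test_positive_governor_excluded(self):
        docs, parses = self._corpus()
        assert "boosts" not in build_anti_positive_list(docs, parses, min_count=1)

    def test_empty_corpus(self):
        assert build_anti_positive_list([], {}, min_count=1) == []


class TestAttachOntologySequences:
    def test_fixture_pair(self, fixture_graph):
        from ontorel.preprocess import attach_ontology_sequences

        pair = CandidatePair("e1", "e2", "negative", "generated", "d", "s")
        concat, common = attach_ontology_sequences(
            pair, {"e1": "T:5", "e2": "T:4"}, fixture_graph
        )
        assert len(concat) == 8
        assert common == ["T:0", "T:1"]

    def test_unlinked_entity_gives_empty_sequences(self, fixture_graph):
        pair = CandidatePair("e1", "e2", "negative", "generated", "d", "s")
        from ontorel.preprocess import attach_ontology_sequences

        assert attach_ontology_sequences(pair, {"e1": "T:5", "e2": None}, fixture_graph) == ([], [])

    def test_same_concept_common_equals_ancestors(self, fixture_graph):
        from ontorel.preprocess import attach_ontology_sequences

        pair = CandidatePair("e1", "e2", "negative", "generated", "d", "s")
        _, common = attach_ontology_sequences(
            pair, {"e1": "T:3", "e2": "T:3"}, fixture_graph
        )
        assert common == fixture_graph.ancestors("T:3")


class TestBuildInstances:
    def _docs(self):
        text = "alpha increases the level of zeta today"
        sent = make_sentence(text, ["alpha", "zeta"], gold=[(0, 1, "effect")])
        return [Document(id="d0", source_type="drugbank", sentences=[sent])]

    def test_pipeline_features(self, fixture_graph):
        instances, auto = build_instances(self._docs(), fixture_graph)
        assert not auto
        (inst,) = instances
        assert inst.pair.label == "effect"
        assert inst.sdp_tokens[0] == "entity" and inst.sdp_tokens[-1] == "entity"
        assert len(inst.sdp_tokens) == len(inst.wordnet_classes)
        # mentions link to T:0 (alpha) and T:5 (zeta)
        assert inst.concat_ancestor_seq == ["T:0"] + fixture_graph.ancestors("T:5")
        assert inst.common_ancestor_seq == ["T:0"]

    def test_no_raw_entity_text_reaches_sdp(self, fixture_graph):
        instances, _ = build_instances(self._docs(), fixture_graph)
        surfaces = {"alpha", "zeta"}
        for inst in instances:
            assert not surfaces & set(inst.sdp_tokens)

    def test_filtering_off_yields_binomial_count(self, fixture_graph):
        docs = self._docs()
        instances, auto = build_instances(docs, fixture_graph, filtering=False)
        assert len(instances) == 1 and not auto


def test_simple_tokenizer_spans_round_trip():
    text = "Response to Plenaxis, measured (daily)."
    for tok in simple_tokenize(text):
        assert text[tok.char_start : tok.char_end + 1] == tok.text
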