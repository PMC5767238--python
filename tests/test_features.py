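"""Discourse measure extraction: tallies, content units, derived ratios."""

import dataclasses

import numpy as np
import pytest

from langsample import (
    ContentUnitLexicon,
    CountSummary,
    MazeEvent,
    Token,
    Transcript,
    CUnit,
    derive_features,
    extract_features,
    generate_transcript,
    match_semantic_units,
    parse_chat,
    random_plan,
    tally_counts,
    write_chat,
)


def counts(**overrides):
    base = dict(
        total_words=50, unique_words=30, n_utterances=5,
        nouns=10, verbs=5, pronouns=5, adjectives=3, adverbs=2,
        prepositions=4, conjunctions=1, determiners=12, other_words=8,
        filled_pauses=2, unfilled_pauses=0, repetitions=1, revisions=1,
        false_starts=0, embedding_relations=3, total_relations=12,
        matched_content_units=8, duration_s=30.0,
    )
    base.update(overrides)
    return CountSummary(**base)


class TestDeriveFeatures:
    def test_worked_example(self):
        fv = derive_features(counts())
        assert fv.pronoun_index == pytest.approx(5 / 15)
        assert fv.verb_index == pytest.approx(1.0)
        assert fv.proposition_density == pytest.approx(0.30)
        assert fv.grammatical_complexity == pytest.approx(0.25)
        assert fv.type_token_ratio == pytest.approx(0.60)
        assert fv.maze_index == pytest.approx(0.8)
        assert fv.mlu == pytest.approx(10.0)
        assert fv.words_per_minute == pytest.approx(100.0)
        assert fv.semantic_units_per_minute == pytest.approx(16.0)
        assert fv.percent_nouns == pytest.approx(20.0)
        assert fv.percent_verbs == pytest.approx(10.0)
        assert fv.total_semantic_units == 8

    def test_zero_pronouns_is_zero_not_missing(self):
        fv = derive_features(counts(pronouns=0, other_words=13))
        assert fv.pronoun_index == 0.0

    def test_zero_maze_events(self):
        fv = derive_features(
            counts(filled_pauses=0, repetitions=0, revisions=0)
        )
        assert fv.maze_index == 0.0

    def test_undefined_ratios_are_missing_not_zero(self):
        fv = derive_features(
            counts(nouns=0, pronouns=0, determiners=22, other_words=13,
                   embedding_relations=0, total_relations=0)
        )
        assert fv.pronoun_index is None
        assert fv.grammatical_complexity is None

    def test_unfilled_pause_option_changes_only_maze_index(self):
        base = derive_features(counts(unfilled_pauses=3))
        alt = derive_features(counts(unfilled_pauses=3), include_unfilled_pauses=True)
        assert alt.maze_index == pytest.approx(base.maze_index + 3 / 5)
        for f in dataclasses.fields(base):
            if f.name != "maze_index":
                assert getattr(alt, f.name) == getattr(base, f.name)


class TestTallyCounts:
    def test_hand_coded_cunit(self, lexicon):
        doc = (
            "@ID:\tp|v\n@Duration:\t30\n"
            "*PAR:\t&-um <the boy> [//] the girl is falling .\n"
            "%mor:\tdeterminer|the noun|girl verb|is verb|fall\n"
        )
        c = tally_counts(parse_chat(doc), lexicon)
        assert c.total_words == 4
        assert c.unique_words == 4
        assert c.filled_pauses == 1
        assert c.revisions == 1
        assert c.nouns == 1 and c.verbs == 2 and c.determiners == 1
        # "girl" and lemma "fall" (stool_falling trigger) both score
        assert c.matched_content_units == 2

    def test_maze_only_transcript_raises(self, lexicon):
        doc = "@ID:\tp|v\n@Duration:\t10\n*PAR:\t&-um <the boy> [//] .\n"
        t = parse_chat(doc)
        with pytest.raises(ValueError, match="empty sample"):
            tally_counts(t, lexicon)

    def test_counts_match_generator_plan(self, lexicon):
        rng = np.random.default_rng(5)
        for _ in range(10):
            plan = random_plan(rng, lexicon)
            t, _ = generate_transcript(plan, lexicon)
            c = tally_counts(t, lexicon)
            totals = plan.pos_totals()
            assert c.total_words == sum(totals.values())
            assert c.nouns == totals["noun"]
            assert c.unique_words == plan.unique_words
            assert c.matched_content_units == plan.n_units()
            assert c.filled_pauses == plan.maze_counts()["filled_pause"]
            assert c.embedding_relations == sum(cu.embeddings for cu in plan.cunits)


class TestSemanticUnits:
    def test_repeated_mention_scores_once(self):
        lex = ContentUnitLexicon({"boy": ["boy"], "girl": ["girl"]})
        cu = CUnit(tokens=[Token(w, w, "noun") for w in ["boy", "boy", "boy"]])
        t = Transcript("p", "v", 10.0, [cu])
        assert match_semantic_units(t, lex) == {"boy"}

    def test_no_lexicon_words_matches_nothing(self):
        lex = ContentUnitLexicon({"boy": ["boy"]})
        cu = CUnit(tokens=[Token(w, w, "noun") for w in ["table", "chair"]])
        t = Transcript("p", "v", 10.0, [cu])
        assert match_semantic_units(t, lex) == set()

    def test_multiword_trigger_on_adjacent_lemmas(self):
        lex = ContentUnitLexicon({"stool_fall": [["stool", "falling"]]})
        cu = CUnit(tokens=[Token(w, w, "noun") for w in ["the", "stool", "falling"]])
        t = Transcript("p", "v", 10.0, [cu])
        assert match_semantic_units(t, lex) == {"stool_fall"}
        # maze material never triggers a unit
        cu2 = CUnit(
            tokens=[
                Token("stool", "stool", "other", in_maze=True),
                Token("falling", "falling", "other", in_maze=True),
                Token("table", "table", "noun"),
            ],
            maze_events=[MazeEvent("revision", 0, 0, 2)],
        )
        t2 = Transcript("p", "v", 10.0, [cu2])
        assert match_semantic_units(t2, lex) == set()


class TestInvariantsOnRandomPlans:
    def test_bounds_and_maze_monotonicity(self, lexicon):
        rng = np.random.default_rng(99)
        for _ in range(15):
            plan = random_plan(rng, lexicon)
            t, fv = generate_transcript(plan, lexicon)
            for name in ("pronoun_index", "proposition_density",
                         "grammatical_complexity", "type_token_ratio"):
                v = getattr(fv, name)
                if v is not None:
                    assert 0.0 <= v <= 1.0
            assert fv.percent_nouns + fv.percent_verbs <= 100.0

            # adding one filled pause raises maze_index by exactly 1/n and
            # leaves every lexical/semantic/syntactic measure unchanged
            t2 = parse_chat(write_chat(t))
            cu = t2.cunits[0]
            cu.tokens.insert(0, Token("um", "um", "nonword", True, True))
            shifted = [
                dataclasses.replace(e, start=e.start + 1, end=e.end + 1)
                for e in cu.maze_events
            ]
            cu.maze_events = [MazeEvent("filled_pause", 0, 0, 1)] + shifted
            cu.relations = [
                dataclasses.replace(r, head_index=r.head_index + 1,
                                    dependent_index=r.dependent_index + 1)
                for r in cu.relations
            ]
            fv2 = extract_features(t2, lexicon)
            assert fv2.maze_index == pytest.approx(
                fv.maze_index + 1 / len(t.cunits)
            )
            for f in dataclasses.fields(fv):
                if f.name != "maze_index":
                    assert getattr(fv2, f.name) == getattr(fv, f.name)
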