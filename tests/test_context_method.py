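"""ConText-style engine: triggers, scopes, sentence-wide modifiers, frames."""

import pytest

from cancerhx.context_method import (
    AXIS_EXPERIENCER,
    AXIS_NEGATION,
    assign_scopes,
    attach_modifiers_sentencewide,
    build_frames_context,
    compile_triggers,
)
from cancerhx.dynamic_window import build_frames_dynamic_window, find_hotspots
from cancerhx.frames import full_phrase
from cancerhx.lexicon import load_lexicon
from cancerhx.parsing import parse_corpus
from cancerhx.synth import (
    SENTENCE_MODIFIER_TRAP,
    SENTENCE_NEG_OUT_OF_REACH,
    SynthSpec,
    generate_corpus,
)

FIG3 = "The patient has no history of small cell lung cancer in her record."


@pytest.fixture(scope="module")
def triggers(lex):
    return compile_triggers(lex)


class TestCompileTriggers:
    def test_negation_phrases_become_triggers(self, triggers):
        phrases = {t.phrase for t in triggers if t.axis == AXIS_NEGATION}
        assert ("denies", "any", "family", "history", "of") in phrases

    def test_kinship_trigger_carries_its_term(self, triggers):
        (mother,) = [t for t in triggers if t.phrase == ("mother",)]
        assert mother.axis == AXIS_EXPERIENCER
        assert mother.value == "mother"

    def test_nonrelatives_valued_discard(self, triggers):
        (spouse,) = [t for t in triggers if t.phrase == ("spouse",)]
        assert spouse.value == "DISCARD"

    def test_empty_negation_category_yields_no_negation_triggers(self, lex):
        data = lex.to_dict()
        data["negation_phrases"] = []
        bare = compile_triggers(load_lexicon(data))
        assert not [t for t in bare if t.axis == AXIS_NEGATION]


class TestAssignScopes:
    def test_negation_scope_covers_concept(self, lex, sentence, triggers):
        s = sentence("no history of small cell lung cancer in her record")
        scopes = assign_scopes(s, triggers)
        concept = s.norms.index("cancer")
        assert any(sc.covers(concept) for sc in scopes[AXIS_NEGATION])

    def test_distant_negation_and_experiencer_both_fire(self, lex, sentence, triggers):
        """The construction the five-token window cannot reach."""
        s = sentence(SENTENCE_NEG_OUT_OF_REACH)
        scopes = assign_scopes(s, triggers)
        concept = s.norms.index("cancer")
        (neg,) = [sc for sc in scopes[AXIS_NEGATION] if sc.covers(concept)]
        assert neg.trigger_text == "no family history of"
        (exp,) = [sc for sc in scopes[AXIS_EXPERIENCER] if sc.covers(concept)]
        assert exp.value == "unknown_family"

    def test_no_triggers_empty_mapping(self, lex, sentence, triggers):
        s = sentence("she has lung cancer today")
        scopes = assign_scopes(s, triggers)
        assert scopes[AXIS_NEGATION] == [] and scopes[AXIS_EXPERIENCER] == []

    def test_termination_token_closes_scope(self, lex, sentence, triggers):
        s = sentence("no fevers but cancer was found")
        scopes = assign_scopes(s, triggers)
        concept = s.norms.index("cancer")
        assert not any(sc.covers(concept) for sc in scopes[AXIS_NEGATION])

    def test_bare_negative_requires_following_for(self, lex, sentence, triggers):
        covered = assign_scopes(sentence("negative for cancer"), triggers)
        assert covered[AXIS_NEGATION]
        ignored = assign_scopes(sentence("review of systems negative"), triggers)
        assert not ignored[AXIS_NEGATION]

    def test_scope_containment(self, lex, sentence, triggers):
        s = sentence(SENTENCE_NEG_OUT_OF_REACH)
        for axis_scopes in assign_scopes(s, triggers).values():
            for sc in axis_scopes:
                assert 0 <= sc.token_start < sc.token_end <= len(s.tokens)


class TestAttachModifiersSentencewide:
    def test_liver_attaches_across_the_sentence(self, lex, sentence):
        s = sentence(SENTENCE_MODIFIER_TRAP)
        (hotspot,) = find_hotspots(s, lex)
        assert attach_modifiers_sentencewide(s, hotspot, lex) == ["liver"]

    def test_adjacent_run_keeps_text_order(self, lex, sentence):
        s = sentence("small cell lung cancer")
        (hotspot,) = find_hotspots(s, lex)
        assert attach_modifiers_sentencewide(s, hotspot, lex) == ["small cell", "lung"]

    def test_no_descriptors_empty(self, lex, sentence):
        s = sentence("the cancer was excised")
        (hotspot,) = find_hotspots(s, lex)
        assert attach_modifiers_sentencewide(s, hotspot, lex) == []


class TestBuildFramesContext:
    def test_modifier_trap_builds_liver_tumor_frame(self, lex, report_of):
        """Documented false positive: distant 'liver' glued onto 'tumor'."""
        report = report_of(f"HPI:\n{SENTENCE_MODIFIER_TRAP}\n")
        (frame,) = build_frames_context(report, lex)
        assert full_phrase(frame) == "liver tumor"
        assert frame.experiencer == "patient"
        assert not frame.is_negated
        # the windowed engine does not reach 'liver'
        (dw_frame,) = build_frames_dynamic_window(report, lex)
        assert full_phrase(dw_frame) == "tumor"

    def test_window_modifier_scope_opts_out_of_trap(self, lex, report_of):
        report = report_of(f"HPI:\n{SENTENCE_MODIFIER_TRAP}\n")
        (frame,) = build_frames_context(report, lex, modifier_scope="window")
        assert full_phrase(frame) == "tumor"

    def test_fig3_example_negated_patient(self, lex, report_of):
        report = report_of(f"HPI:\n{FIG3}\n")
        (frame,) = build_frames_context(report, lex)
        assert frame.is_negated
        assert frame.experiencer == "patient"
        assert full_phrase(frame) == "small cell lung cancer"

    def test_distant_negation_found_where_window_engine_misses(self, lex, report_of):
        report = report_of(f"HPI:\n{SENTENCE_NEG_OUT_OF_REACH}\n")
        (ctx_frame,) = build_frames_context(report, lex)
        assert ctx_frame.is_negated
        assert ctx_frame.experiencer == "unknown_family"
        (dw_frame,) = build_frames_dynamic_window(report, lex)
        assert not dw_frame.is_negated

    def test_nonrelative_scope_discards_frame(self, lex, report_of):
        report = report_of("HPI:\nHer husband has lung cancer.\n")
        assert build_frames_context(report, lex) == []

    def test_family_history_section_default(self, lex, report_of):
        report = report_of("FAMILY HISTORY:\nThere is leukemia in the family.\n")
        (frame,) = build_frames_context(report, lex)
        assert frame.experiencer == "unknown_family"

    def test_empty_report(self, lex, report_of):
        assert build_frames_context(report_of("HPI:\nStable.\n"), lex) == []

    def test_invalid_modifier_scope_rejected(self, lex, report_of):
        with pytest.raises(ValueError, match="modifier_scope"):
            build_frames_context(report_of("HPI:\nx.\n"), lex, modifier_scope="bogus")


def test_cross_engine_agreement_on_easy_corpus(lex):
    """Where negation sits within window reach and no distant descriptors
    lurk, both engines must emit identical (term, negated, experiencer)
    triples for every frame."""
    corpus, _ = generate_corpus(SynthSpec(n_reports=60, seed=11, hardness="easy"))
    for report in parse_corpus(corpus, lex):
        dw = [(f.cancer_term, f.is_negated, f.experiencer)
              for f in build_frames_dynamic_window(report, lex)]
        ctx = [(f.cancer_term, f.is_negated, f.experiencer)
               for f in build_frames_context(report, lex)]
        assert dw == ctx, report.report_id
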