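"""Dynamic-Window engine: hot-spots, window searches, experiencer, frames."""

import random

import pytest

from cancerhx.dynamic_window import (
    DISCARD,
    WindowConfig,
    build_frames_dynamic_window,
    determine_experiencer,
    expand_hotspot,
    find_hotspots,
    search_modifiers,
    search_negation,
    window_before,
)
from cancerhx.frames import full_phrase
from cancerhx.lexicon import segmentable_as_modifiers
from cancerhx.parsing import split_sentences

EXAMPLE = "The patient has no history of small cell lung cancer in her record."
REPORT_113 = "There is no family history of diabetes or cancer."


def only_hotspot(sentence, lex):
    hotspots = find_hotspots(sentence, lex)
    assert len(hotspots) == 1
    return hotspots[0]


class TestFindHotspots:
    def test_cancer_word_fallback(self, lex, sentence):
        hotspot = only_hotspot(sentence(EXAMPLE), lex)
        assert hotspot.term == "cancer"
        assert hotspot.rule == "cancer_word"

    def test_noncancer_oma_excluded(self, lex, sentence):
        assert find_hotspots(sentence("a hematoma on her leg"), lex) == []

    def test_adjective_noun_suppression(self, lex, sentence):
        assert find_hotspots(sentence("tumor markers were normal"), lex) == []
        assert find_hotspots(sentence("seen at the cancer conference"), lex) == []

    def test_oma_suppresses_cancer_word_search(self, lex, sentence):
        hotspots = find_hotspots(
            sentence("mesothelioma versus signet-ring cell adenocarcinoma"), lex
        )
        assert [h.term for h in hotspots] == ["mesothelioma", "adenocarcinoma"]

    def test_unique_cancer_found_alongside_oma(self, lex, sentence):
        hotspots = find_hotspots(sentence("mesothelioma and a neoplasm"), lex)
        assert {h.term for h in hotspots} == {"mesothelioma", "neoplasm"}

    def test_acronym_exact_case(self, lex, sentence):
        assert [h.term for h in find_hotspots(sentence("treated for SCLC today"), lex)] == ["SCLC"]
        # lowercase determiner must not match acronym ALL
        assert find_hotspots(sentence("she took all her pills"), lex) == []

    def test_melanoma_is_both_descriptor_and_hotspot(self, lex, sentence):
        assert [h.term for h in find_hotspots(sentence("history of melanoma"), lex)] == ["melanoma"]


class TestWindowBefore:
    def test_full_window(self, lex, sentence):
        s = sentence(EXAMPLE)
        hotspot = only_hotspot(s, lex)
        norms = [t.norm for t in window_before(s.tokens, hotspot.token_start, 5)]
        assert norms == ["history", "of", "small", "cell", "lung"]

    def test_size_three(self, lex, sentence):
        s = sentence(EXAMPLE)
        hotspot = only_hotspot(s, lex)
        norms = [t.norm for t in window_before(s.tokens, hotspot.token_start, 3)]
        assert norms == ["small", "cell", "lung"]

    def test_truncated_at_sentence_start(self, lex, sentence):
        s = sentence("cancer was found")
        assert window_before(s.tokens, 0, 4) == ()


class TestSearchModifiers:
    def test_worked_example_matches_at_size_3(self, lex, sentence):
        s = sentence(EXAMPLE)
        match = search_modifiers(s, only_hotspot(s, lex), None, lex)
        assert match.direction == "backward"
        assert match.window_size == 3
        assert match.phrases == ("small cell", "lung")

    def test_forward_location_pattern(self, lex, sentence):
        s = sentence("cancer of the lung")
        match = search_modifiers(s, only_hotspot(s, lex), None, lex)
        assert match.direction == "forward"
        assert match.window_size == 3
        assert match.phrases == ("lung",)

    def test_generic_mention_no_modifiers(self, lex, sentence):
        s = sentence("The cancer was excised 6 months ago")
        assert search_modifiers(s, only_hotspot(s, lex), None, lex) is None

    def test_larger_window_precedence(self, lex, sentence):
        s = sentence("malignant small cell lung cancer")
        match = search_modifiers(s, only_hotspot(s, lex), None, lex)
        assert match.window_size == 4
        assert match.phrases == ("malignant", "small cell", "lung")


class TestExpandAndNegate:
    def test_backward_match_expands_hotspot(self, lex, sentence):
        s = sentence(EXAMPLE)
        hotspot = only_hotspot(s, lex)
        match = search_modifiers(s, hotspot, None, lex)
        expanded = expand_hotspot(hotspot, match)
        assert expanded.expanded
        assert expanded.token_start == hotspot.token_start - 3

    def test_forward_match_does_not_expand(self, lex, sentence):
        s = sentence("cancer of the lung")
        hotspot = only_hotspot(s, lex)
        match = search_modifiers(s, hotspot, None, lex)
        assert expand_hotspot(hotspot, match) == hotspot

    def test_no_match_identity(self, lex, sentence):
        s = sentence("The cancer was excised")
        hotspot = only_hotspot(s, lex)
        assert expand_hotspot(hotspot, None) == hotspot

    def test_negation_found_after_expansion(self, lex, sentence):
        s = sentence(EXAMPLE)
        hotspot = only_hotspot(s, lex)
        expanded = expand_hotspot(hotspot, search_modifiers(s, hotspot, None, lex))
        negation = search_negation(s, expanded, None, lex)
        assert negation.phrase == "no history of"
        assert negation.window_size == 3

    def test_negation_out_of_reach_documented_miss(self, lex, sentence):
        s = sentence(REPORT_113)
        hotspot = only_hotspot(s, lex)
        expanded = expand_hotspot(hotspot, search_modifiers(s, hotspot, None, lex))
        assert search_negation(s, expanded, None, lex) is None

    def test_sentence_initial_hotspot_unnegated(self, lex, sentence):
        s = sentence("cancer was excised")
        assert search_negation(s, only_hotspot(s, lex), None, lex) is None


class TestDetermineExperiencer:
    def test_family_history_section_defaults_unknown_family(
        self, lex, sentence, fh_section
    ):
        s = sentence("There is a history of cancer.")
        assert determine_experiencer(s, fh_section, lex) == "unknown_family"

    def test_kinship_term_names_relative(self, lex, sentence, subjective_section):
        s = sentence("His mother had breast cancer.")
        assert determine_experiencer(s, subjective_section, lex) == "mother"

    def test_nonrelative_discards(self, lex, sentence, subjective_section):
        s = sentence("His wife has lung cancer.")
        assert determine_experiencer(s, subjective_section, lex) == DISCARD

    def test_family_history_phrase_with_kinship_refines(
        self, lex, sentence, subjective_section
    ):
        s = sentence("Family history of cancer in her aunt.")
        assert determine_experiencer(s, subjective_section, lex) == "aunt"

    def test_default_patient(self, lex, sentence, subjective_section):
        s = sentence("She has lung cancer.")
        assert determine_experiencer(s, subjective_section, lex) == "patient"


class TestBuildFrames:
    def test_worked_example_frame(self, lex, report_of):
        report = report_of(f"HPI:\n{EXAMPLE}\n")
        (frame,) = build_frames_dynamic_window(report, lex)
        assert frame.cancer_term == "cancer"
        assert frame.modifiers == ("small cell", "lung")
        assert frame.negation_terms == ("no history of",)
        assert frame.experiencer == "patient"
        assert full_phrase(frame) == "small cell lung cancer"

    def test_nonsubjective_sections_skipped(self, lex, report_of):
        report = report_of("PHYSICAL EXAMINATION:\nmass suspicious for carcinoma\n")
        assert build_frames_dynamic_window(report, lex) == []

    def test_empty_report_no_frames(self, lex, report_of):
        assert build_frames_dynamic_window(report_of("HPI:\nStable.\n"), lex) == []

    def test_report_113_regression_unreached_negation(self, lex, report_of):
        """The documented false positive: negation beyond window reach."""
        report = report_of(f"HPI:\n{REPORT_113}\n")
        (frame,) = build_frames_dynamic_window(report, lex)
        assert frame.cancer_term == "cancer"
        assert not frame.is_negated  # expected miss, asserted as behavior
        assert frame.experiencer == "unknown_family"

    def test_determinism(self, lex, report_of):
        report = report_of(f"HPI:\n{EXAMPLE}\nFAMILY HISTORY:\nFather had melanoma.\n")
        a = build_frames_dynamic_window(report, lex)
        b = build_frames_dynamic_window(report, lex)
        assert a == b


# ---------------------------------------------------------------------------
# Brute-force oracle for the windowed searches.

VOCAB = ["small", "cell", "lung", "breast", "no", "history", "of", "denies",
         "any", "the", "patient", "has", "malignant", "without", "a",
         "family", "her", "record", "liver", "negative", "for"]


def brute_partitionable(tokens, descriptors):
    if not tokens:
        return True
    return any(
        " ".join(tokens[:k]) in descriptors
        and brute_partitionable(tokens[k:], descriptors)
        for k in range(1, len(tokens) + 1)
    )


def oracle_modifier_window(norms, anchor, lex):
    """Enumerate contiguous preceding subsequences, largest first."""
    for size in (5, 4, 3, 2, 1):
        if anchor - size < 0:
            continue
        window = norms[anchor - size : anchor]
        if brute_partitionable(window, lex.modifier_descriptors):
            return ("backward", size)
    for offset in (1, 2, 3):
        if anchor + offset < len(norms) and norms[anchor + offset] in lex.modifier_descriptors:
            return ("forward", offset)
    return None


def oracle_negation_window(norms, start, lex):
    for size in (5, 4, 3, 2, 1):
        if start - size < 0:
            continue
        if " ".join(norms[start - size : start]) in lex.negation_phrases:
            return size
    return None


def test_window_searches_match_brute_force_oracle(lex):
    """Windowed modifier/negation search equals exhaustive enumeration."""
    rng = random.Random(20260927)
    checked = 0
    for _ in range(400):
        n = rng.randint(1, 15)
        words = [rng.choice(VOCAB) for _ in range(n)]
        anchor = rng.randrange(n + 1)
        words.insert(anchor, "cancer")
        s = split_sentences(" ".join(words))[0]
        hotspots = [h for h in find_hotspots(s, lex) if h.term == "cancer"]
        if not hotspots:
            continue  # suppressed or absorbed; not the searched situation
        hotspot = hotspots[0]
        norms = list(s.norms)

        expected = oracle_modifier_window(norms, hotspot.token_start, lex)
        match = search_modifiers(s, hotspot, None, lex)
        got = None if match is None else (match.direction, match.window_size)
        assert got == expected, (words, hotspot)

        expanded = expand_hotspot(hotspot, match)
        expected_neg = oracle_negation_window(norms, expanded.token_start, lex)
        negation = search_negation(s, expanded, None, lex)
        got_neg = None if negation is None else negation.window_size
        assert got_neg == expected_neg, (words, hotspot)
        checked += 1
    assert checked > 300


def test_window_config_validation():
    with pytest.raises(ValueError):
        WindowConfig(backward_sizes=(3, 4))
    with pytest.raises(ValueError):
        WindowConfig(backward_sizes=(3, 0))
    cfg = WindowConfig(backward_sizes=(7, 5, 3))
    assert cfg.backward_sizes == (7, 5, 3)
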