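"""Dynamic-Window frame builder.

Builds cancer frames in five steps per subjective sentence:

1. locate cancer-concept "hot-spots" (``-oma`` suffix words, the word
   "cancer" as a fallback, unique cancer words, acronyms);
2. search for modifier phrases with a variable-size bi-directional window
   (backward windows of 5..1 tokens, each of which must match the modifier
   lexicon in its entirety, then a forward look of three single-token
   offsets for the "cancer of the <location>" pattern);
3. expand the hot-spot backward over any backward-matched modifiers;
4. search backward from the (expanded) hot-spot for a negation phrase with
   the same descending window sizes (no forward look);
5. determine the experiencer (patient by default; family-history section or
   phrase, kinship terms, and nonrelative discard rules).

Windows never cross sentence boundaries, and a larger matching window always
wins over a smaller one.  The fixed maximum window of five tokens is a known,
deliberate limitation: a negation phrase pushed more than five tokens from
the (expanded) hot-spot — e.g. by an intervening prepositional phrase — is
out of reach and the frame comes out non-negated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .frames import (
    EXPERIENCER_PATIENT,
    EXPERIENCER_UNKNOWN_FAMILY,
    CancerFrame,
)
from .lexicon import Lexicon, default_lexicon, segment_modifiers
from .parsing import Report, Section, Sentence, TokenSpan

__all__ = [
    "DISCARD",
    "Hotspot",
    "ModifierMatch",
    "NegationMatch",
    "WindowConfig",
    "build_frames_dynamic_window",
    "determine_experiencer",
    "expand_hotspot",
    "find_hotspots",
    "search_modifiers",
    "search_negation",
    "window_before",
]

logger = logging.getLogger(__name__)

#: Sentinel experiencer for frames attributed to a nonrelative (dropped).
DISCARD = "DISCARD"

_FAMILY_PHRASES = (("family", "history", "of"), ("family", "history"))


@dataclass(frozen=True)
class Hotspot:
    """A located cancer-concept token span anchoring the window searches."""

    token_start: int
    token_end: int  # half-open
    term: str
    rule: str  # oma_suffix | cancer_word | unique_cancer | acronym
    expanded: bool = False

    def __post_init__(self):
        if not self.token_start < self.token_end:
            raise ValueError("hotspot span must be non-empty")


@dataclass(frozen=True)
class WindowConfig:
    """Window-search geometry.

    ``backward_sizes`` are tried largest first; each window must match the
    lexicon in full.  ``forward_look_offsets`` are single-token look-aheads
    (window size 1) used only for modifiers.
    """

    backward_sizes: tuple[int, ...] = (5, 4, 3, 2, 1)
    forward_look_offsets: tuple[int, ...] = (1, 2, 3)
    forward_window_size: int = 1

    def __post_init__(self):
        if any(s < 1 for s in self.backward_sizes + self.forward_look_offsets):
            raise ValueError("window sizes and offsets must be >= 1")
        if list(self.backward_sizes) != sorted(set(self.backward_sizes), reverse=True):
            raise ValueError("backward_sizes must be strictly descending")
        if self.forward_window_size < 1:
            raise ValueError("forward_window_size must be >= 1")


@dataclass(frozen=True)
class ModifierMatch:
    phrases: tuple[str, ...]   # lexicon-phrase units, text order
    direction: str             # "backward" | "forward"
    window_size: int           # matched backward size, or forward offset
    token_start: int           # first token of the matched modifier span
    token_end: int


@dataclass(frozen=True)
class NegationMatch:
    phrase: str
    window_size: int


def _is_oma(norm: str, lex: Lexicon) -> bool:
    if norm in lex.noncancer_oma_terms:
        return False
    if norm.endswith("omas") and norm[:-1] in lex.noncancer_oma_terms:
        return False
    return (norm.endswith("oma") or norm.endswith("omas")) and len(norm) > 3


def find_hotspots(sentence: Sentence, lex: Lexicon | None = None) -> list[Hotspot]:
    """Step 1: cancer-concept identification cascade.

    ``-oma``/``-omas`` suffix words (minus the non-cancer list) are found
    first; only if none exist is the literal word "cancer" searched.  Unique
    cancer words and (exact-case) acronyms are searched unconditionally.  A
    candidate immediately followed by a cancer-as-adjective noun ("tumor
    markers", "cancer conference") is suppressed.
    """
    lex = lex or default_lexicon()
    tokens = sentence.tokens
    found: dict[int, Hotspot] = {}

    def add(i: int, term: str, rule: str):
        if i not in found:
            found[i] = Hotspot(i, i + 1, term, rule)

    oma_indices = [i for i, t in enumerate(tokens) if _is_oma(t.norm, lex)]
    for i in oma_indices:
        add(i, tokens[i].norm, "oma_suffix")
    if not oma_indices:
        for i, t in enumerate(tokens):
            if t.norm == "cancer":
                add(i, t.norm, "cancer_word")
    for i, t in enumerate(tokens):
        if t.norm in lex.unique_cancers:
            add(i, t.norm, "unique_cancer")
    for i, t in enumerate(tokens):
        if t.stripped in lex.cancer_acronyms:
            add(i, t.stripped, "acronym")

    hotspots = []
    for i in sorted(found):
        nxt = i + 1
        if nxt < len(tokens) and tokens[nxt].norm in lex.cancer_as_adjective_nouns:
            logger.debug("hotspot %r suppressed by adjective noun %r",
                         found[i].term, tokens[nxt].norm)
            continue
        hotspots.append(found[i])
    return hotspots


def window_before(
    tokens: Sequence[TokenSpan], anchor_start: int, size: int
) -> tuple[TokenSpan, ...]:
    """Up to ``size`` tokens immediately preceding ``anchor_start``.

    Truncated at the sentence start; never crosses a sentence boundary.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    lo = max(0, anchor_start - size)
    return tuple(tokens[lo:anchor_start])


def search_modifiers(
    sentence: Sentence,
    hotspot: Hotspot,
    cfg: WindowConfig | None = None,
    lex: Lexicon | None = None,
) -> ModifierMatch | None:
    """Step 2: variable-size bi-directional modifier search.

    Backward window sizes are tried in descending order; the first window
    that is *entirely* segmentable into modifier-descriptor phrases wins
    (a window shorter than its nominal size — truncated at sentence start —
    is deferred to the matching smaller size).  If no backward window
    matches, each forward offset's single token is tested; the first
    descriptor hit wins.
    """
    cfg = cfg or WindowConfig()
    lex = lex or default_lexicon()
    tokens = sentence.tokens

    for size in cfg.backward_sizes:
        window = window_before(tokens, hotspot.token_start, size)
        if len(window) != size:
            continue
        phrases = segment_modifiers([t.norm for t in window], lex)
        if phrases is not None:
            logger.debug("modifiers %r matched at backward window %d", phrases, size)
            return ModifierMatch(
                phrases=tuple(phrases),
                direction="backward",
                window_size=size,
                token_start=hotspot.token_start - size,
                token_end=hotspot.token_start,
            )

    for offset in cfg.forward_look_offsets:
        idx = hotspot.token_end - 1 + offset
        if idx >= len(tokens):
            continue
        norm = tokens[idx].norm
        if norm in lex.modifier_descriptors:
            logger.debug("modifier %r matched at forward offset %d", norm, offset)
            return ModifierMatch(
                phrases=(norm,),
                direction="forward",
                window_size=offset,
                token_start=idx,
                token_end=idx + 1,
            )
    return None


def expand_hotspot(hotspot: Hotspot, match: ModifierMatch | None) -> Hotspot:
    """Step 3: expand the hot-spot backward over backward-matched modifiers.

    Forward matches and misses leave the hot-spot unchanged — only a
    backward modifier run becomes part of the unified concept span.
    """
    if match is None or match.direction != "backward":
        return hotspot
    return replace(hotspot, token_start=match.token_start, expanded=True)


def search_negation(
    sentence: Sentence,
    hotspot: Hotspot,
    cfg: WindowConfig | None = None,
    lex: Lexicon | None = None,
) -> NegationMatch | None:
    """Step 4: backward-only negation search from the (expanded) span start.

    The first descending window whose full token sequence is a negation
    phrase wins; there is no forward look.
    """
    cfg = cfg or WindowConfig()
    lex = lex or default_lexicon()
    tokens = sentence.tokens

    for size in cfg.backward_sizes:
        window = window_before(tokens, hotspot.token_start, size)
        if len(window) != size:
            continue
        phrase = " ".join(t.norm for t in window)
        if phrase in lex.negation_phrases:
            logger.debug("negation %r matched at backward window %d", phrase, size)
            return NegationMatch(phrase=phrase, window_size=size)
    return None


def _find_phrase(norms: Sequence[str], phrases: Sequence[tuple[str, ...]]) -> int | None:
    """Leftmost start index of any of the given token-tuple phrases."""
    best = None
    for phrase in phrases:
        k = len(phrase)
        for i in range(len(norms) - k + 1):
            if tuple(norms[i : i + k]) == phrase:
                if best is None or i < best:
                    best = i
                break
    return best


def _scan_kinship(norms: Sequence[str], lex: Lexicon) -> str | None:
    """Leftmost kinship term; first-degree relatives take precedence."""
    for category in ("kinship_fdr", "kinship_other"):
        phrases = [tuple(p.split()) for p in lex.category(category)]
        idx = _find_phrase(norms, phrases)
        if idx is not None:
            best = None
            for phrase in phrases:
                k = len(phrase)
                if tuple(norms[idx : idx + k]) == phrase:
                    if best is None or len(phrase) > len(best):
                        best = phrase
            return " ".join(best)
    return None


def determine_experiencer(
    sentence: Sentence, section: Section, lex: Lexicon | None = None
) -> str:
    """Step 5: who experiences the cancer.

    Defaults to the patient.  A family-history section (rule A) or the
    phrase "family history (of)" in the sentence (rule B) switches to
    "unknown_family", refined to a specific kinship term if one appears.
    Outside those rules, a nonrelative mention discards the frame
    (:data:`DISCARD`) and a kinship mention names the relative.
    """
    lex = lex or default_lexicon()
    norms = sentence.norms

    family_context = section.is_family_history or (
        _find_phrase(norms, _FAMILY_PHRASES) is not None
    )
    if family_context:
        kin = _scan_kinship(norms, lex)
        return kin if kin is not None else EXPERIENCER_UNKNOWN_FAMILY

    nonrel = [tuple(p.split()) for p in lex.nonrelatives]
    if _find_phrase(norms, nonrel) is not None:
        return DISCARD
    kin = _scan_kinship(norms, lex)
    if kin is not None:
        return kin
    return EXPERIENCER_PATIENT


def build_frames_dynamic_window(
    report: Report,
    lex: Lexicon | None = None,
    cfg: WindowConfig | None = None,
) -> list[CancerFrame]:
    """Run steps 1-5 over every subjective sentence of a parsed report."""
    lex = lex or default_lexicon()
    cfg = cfg or WindowConfig()
    frames = []
    for section, sentence in report.subjective_sentences():
        hotspots = find_hotspots(sentence, lex)
        if not hotspots:
            continue
        experiencer = determine_experiencer(sentence, section, lex)
        if experiencer == DISCARD:
            logger.debug("frames in %r discarded: nonrelative experiencer",
                         sentence.text)
            continue
        for hotspot in hotspots:
            match = search_modifiers(sentence, hotspot, cfg, lex)
            expanded = expand_hotspot(hotspot, match)
            negation = search_negation(sentence, expanded, cfg, lex)
            frames.append(
                CancerFrame(
                    report_id=report.report_id,
                    cancer_term=hotspot.term,
                    modifiers=match.phrases if match else (),
                    experiencer=experiencer,
                    negation_terms=(negation.phrase,) if negation else (),
                    section_location=section.location,
                    sentence_text=sentence.text,
                )
            )
    return frames
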