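"""ConText-style frame builder: trigger phrases with forward sentence scope.

In the NegEx/ConText family, a trigger phrase (negation cue, experiencer
cue) opens a *scope* running from the token after the trigger to the end of
the sentence, closed early by a termination conjunction or superseded by a
later trigger on the same axis.  Any cancer concept inside a negation scope
is negated; inside an experiencer scope it is attributed to that scope's
value (a relative, "unknown family", or a nonrelative, which discards the
frame).

Hot-spot identification is shared with the Dynamic-Window engine; the two
builders differ in how they attach negation, experiencer and modifiers.
Modifier attachment is sentence-wide by default: every modifier-descriptor
occurrence in the sentence (outside the hot-spot) attaches to the concept.
That long reach is deliberately preserved — it repairs negation phrases the
five-token window cannot reach, but it also famously fabricates concepts by
gluing a distant anatomic word onto a generic term ("tumor ... ultrasound of
the liver" -> a "liver tumor" frame).  Set ``modifier_scope="window"`` to use
the windowed modifier search instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .dynamic_window import (
    DISCARD,
    Hotspot,
    WindowConfig,
    find_hotspots,
    search_modifiers,
)
from .frames import (
    EXPERIENCER_PATIENT,
    EXPERIENCER_UNKNOWN_FAMILY,
    CancerFrame,
)
from .lexicon import Lexicon, default_lexicon
from .parsing import Report, Sentence

__all__ = [
    "AXIS_EXPERIENCER",
    "AXIS_NEGATION",
    "TERMINATION_TOKENS",
    "Scope",
    "Trigger",
    "assign_scopes",
    "attach_modifiers_sentencewide",
    "build_frames_context",
    "compile_triggers",
]

logger = logging.getLogger(__name__)

AXIS_NEGATION = "negation"
AXIS_EXPERIENCER = "experiencer"

#: Conjunctions that close every open scope (ConText-family convention).
TERMINATION_TOKENS = frozenset({"but", "however", "although"})

#: Bare cue words that only act as triggers when followed by "for"
#: ("negative for ...", "unremarkable for ..."); a trailing "ROS negative."
#: is a post-concept occurrence and is ignored.
_REQUIRES_FOR = frozenset({"negative", "unremarkable"})


@dataclass(frozen=True)
class Trigger:
    phrase: tuple[str, ...]
    axis: str
    value: str  # "negated" | experiencer label | DISCARD
    requires_following_for: bool = False

    def __post_init__(self):
        if not self.phrase:
            raise ValueError("trigger phrase must be non-empty")
        if self.axis not in (AXIS_NEGATION, AXIS_EXPERIENCER):
            raise ValueError(f"unknown trigger axis {self.axis!r}")


@dataclass(frozen=True)
class Scope:
    token_start: int
    token_end: int  # half-open, bounded by sentence length
    axis: str
    value: str
    trigger_text: str = ""

    def __post_init__(self):
        if not self.token_start < self.token_end:
            raise ValueError("scope must be non-empty")

    def covers(self, index: int) -> bool:
        return self.token_start <= index < self.token_end


def compile_triggers(lex: Lexicon | None = None) -> list[Trigger]:
    """Build the trigger inventory from the domain lexicon.

    Negation phrases become negation triggers; "family history (of)" and
    kinship terms become experiencer triggers; nonrelatives become
    DISCARD-valued experiencer triggers.  Only pre-concept (forward-scoping)
    triggers are compiled.
    """
    lex = lex or default_lexicon()
    triggers = []
    for phrase in sorted(lex.negation_phrases):
        tokens = tuple(phrase.split())
        triggers.append(
            Trigger(
                phrase=tokens,
                axis=AXIS_NEGATION,
                value="negated",
                requires_following_for=tokens in {(w,) for w in _REQUIRES_FOR},
            )
        )
    triggers.append(
        Trigger(("family", "history"), AXIS_EXPERIENCER, EXPERIENCER_UNKNOWN_FAMILY)
    )
    triggers.append(
        Trigger(
            ("family", "history", "of"), AXIS_EXPERIENCER, EXPERIENCER_UNKNOWN_FAMILY
        )
    )
    for category in ("kinship_fdr", "kinship_other"):
        for phrase in sorted(lex.category(category)):
            triggers.append(
                Trigger(tuple(phrase.split()), AXIS_EXPERIENCER, phrase)
            )
    for phrase in sorted(lex.nonrelatives):
        triggers.append(Trigger(tuple(phrase.split()), AXIS_EXPERIENCER, DISCARD))
    return triggers


def _match_at(
    norms: Sequence[str], i: int, triggers: Sequence[Trigger], axis: str
) -> Trigger | None:
    """Longest trigger of ``axis`` whose phrase starts at token ``i``."""
    best = None
    for trigger in triggers:
        if trigger.axis != axis:
            continue
        k = len(trigger.phrase)
        if tuple(norms[i : i + k]) != trigger.phrase:
            continue
        if trigger.requires_following_for and (
            i + k >= len(norms) or norms[i + k] != "for"
        ):
            continue
        if best is None or len(trigger.phrase) > len(best.phrase):
            best = trigger
    return best


def assign_scopes(
    sentence: Sentence, triggers: Sequence[Trigger]
) -> dict[str, list[Scope]]:
    """Assign forward scopes for every trigger occurrence in the sentence.

    Each trigger opens a scope from the token after its phrase to the end of
    the sentence; a termination token closes all open scopes, and a later
    trigger on the same axis supersedes the earlier one from its own start.
    Returned scopes are clipped to their effective extent, so for any token
    index at most one scope per axis covers it.
    """
    norms = sentence.norms
    n = len(norms)
    scopes: dict[str, list[Scope]] = {AXIS_NEGATION: [], AXIS_EXPERIENCER: []}
    open_scope: dict[str, tuple[int, str, str] | None] = {
        AXIS_NEGATION: None,
        AXIS_EXPERIENCER: None,
    }

    def close(axis: str, end: int):
        pending = open_scope[axis]
        if pending is not None:
            start, value, text = pending
            if start < end:
                scopes[axis].append(Scope(start, end, axis, value, text))
            open_scope[axis] = None

    # Axes scan independently so that e.g. the experiencer trigger "family
    # history of" nested inside the negation trigger "no family history of"
    # still fires; within one axis, tokens inside a matched trigger phrase
    # are not re-scanned.
    next_allowed = {AXIS_NEGATION: 0, AXIS_EXPERIENCER: 0}
    for i in range(n):
        if norms[i] in TERMINATION_TOKENS:
            close(AXIS_NEGATION, i)
            close(AXIS_EXPERIENCER, i)
            continue
        for axis in (AXIS_NEGATION, AXIS_EXPERIENCER):
            if i < next_allowed[axis]:
                continue
            trigger = _match_at(norms, i, triggers, axis)
            if trigger is not None:
                close(axis, i)
                open_scope[axis] = (
                    i + len(trigger.phrase),
                    trigger.value,
                    " ".join(trigger.phrase),
                )
                next_allowed[axis] = i + len(trigger.phrase)
    close(AXIS_NEGATION, n)
    close(AXIS_EXPERIENCER, n)
    return scopes


def _scope_value(scopes: dict[str, list[Scope]], axis: str, index: int) -> str | None:
    for scope in scopes[axis]:
        if scope.covers(index):
            return scope.value
    return None


def attach_modifiers_sentencewide(
    sentence: Sentence, hotspot: Hotspot, lex: Lexicon | None = None
) -> list[str]:
    """Attach every modifier-descriptor occurrence in the sentence.

    Greedy longest-phrase matching over the tokens outside the hot-spot
    span.  Ordering: the contiguous run of descriptors immediately before
    the hot-spot keeps its text order (so "small cell lung cancer" reads
    correctly), then remaining matches by increasing distance from the
    hot-spot.
    """
    lex = lex or default_lexicon()
    norms = sentence.norms
    n = len(norms)
    maxlen = lex.max_descriptor_len

    matches: list[tuple[int, int, str]] = []  # (start, end, phrase)
    i = 0
    while i < n:
        if hotspot.token_start <= i < hotspot.token_end:
            i += 1
            continue
        hit = None
        for length in range(min(maxlen, n - i), 0, -1):
            if i < hotspot.token_start and i + length > hotspot.token_start:
                continue  # never straddle the hot-spot
            candidate = " ".join(norms[i : i + length])
            if candidate in lex.modifier_descriptors:
                hit = (i, i + length, candidate)
                break
        if hit:
            matches.append(hit)
            i = hit[1]
        else:
            i += 1

    # Contiguous pre-hot-spot run, in text order.
    adjacent: list[tuple[int, int, str]] = []
    boundary = hotspot.token_start
    for match in sorted(matches, key=lambda m: -m[0]):
        if match[1] == boundary:
            adjacent.insert(0, match)
            boundary = match[0]
    rest = [m for m in matches if m not in adjacent]

    def distance(match: tuple[int, int, str]) -> int:
        start, end, _ = match
        if end <= hotspot.token_start:
            return hotspot.token_start - end
        return start - hotspot.token_end

    rest.sort(key=lambda m: (distance(m), m[0]))
    return [m[2] for m in adjacent] + [m[2] for m in rest]


def build_frames_context(
    report: Report,
    lex: Lexicon | None = None,
    modifier_scope: str = "sentence",
    cfg: WindowConfig | None = None,
) -> list[CancerFrame]:
    """Build frames with trigger/scope negation and experiencer attribution.

    ``modifier_scope`` selects sentence-wide descriptor attachment (the
    evaluated default) or the windowed search ("window").
    """
    if modifier_scope not in ("sentence", "window"):
        raise ValueError(f"modifier_scope must be 'sentence' or 'window', "
                         f"got {modifier_scope!r}")
    lex = lex or default_lexicon()
    triggers = compile_triggers(lex)
    frames = []
    for section, sentence in report.subjective_sentences():
        hotspots = find_hotspots(sentence, lex)
        if not hotspots:
            continue
        scopes = assign_scopes(sentence, triggers)
        for hotspot in hotspots:
            negation = _scope_value(scopes, AXIS_NEGATION, hotspot.token_start)
            experiencer = _scope_value(scopes, AXIS_EXPERIENCER, hotspot.token_start)
            if experiencer is None:
                experiencer = (
                    EXPERIENCER_UNKNOWN_FAMILY
                    if section.is_family_history
                    else EXPERIENCER_PATIENT
                )
            if experiencer == DISCARD:
                logger.debug("frame %r discarded: nonrelative scope", hotspot.term)
                continue
            if modifier_scope == "sentence":
                modifiers = tuple(attach_modifiers_sentencewide(sentence, hotspot, lex))
            else:
                match = search_modifiers(sentence, hotspot, cfg, lex)
                modifiers = match.phrases if match else ()
            neg_terms = ()
            if negation is not None:
                neg_terms = (_negation_phrase(sentence, scopes, hotspot),)
            frames.append(
                CancerFrame(
                    report_id=report.report_id,
                    cancer_term=hotspot.term,
                    modifiers=modifiers,
                    experiencer=experiencer,
                    negation_terms=neg_terms,
                    section_location=section.location,
                    sentence_text=sentence.text,
                )
            )
    return frames


def _negation_phrase(
    sentence: Sentence, scopes: dict[str, list[Scope]], hotspot: Hotspot
) -> str:
    """The trigger text of the negation scope covering the hot-spot."""
    for scope in scopes[AXIS_NEGATION]:
        if scope.covers(hotspot.token_start) and scope.trigger_text:
            return scope.trigger_text
    return "negated"
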