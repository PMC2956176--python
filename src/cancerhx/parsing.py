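"""Structural decomposition of a report corpus.

A corpus file holds one or more de-identified history-and-physical (H&P)
reports separated by a delimiter line.  Each report is split into sections at
heading lines, sections into sentences, and sentences into position-tracked
tokens.  Clinical notes follow the subjective/objective/assessment/plan
convention; downstream frame builders only see sentences from *subjective*
sections (everything whose heading is not on the non-subjective list), which
keeps physical-exam and assessment text out of the search space.

Coordinates are 0-based: character offsets are half-open into the sentence
text, token positions are indices within the sentence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import Lexicon, default_lexicon

__all__ = [
    "DEFAULT_DELIMITER",
    "DEFAULT_SUBJECTIVE_HEADINGS",
    "Report",
    "Section",
    "Sentence",
    "TokenSpan",
    "parse_corpus",
    "parse_report",
    "segment_sections",
    "split_corpus",
    "split_sentences",
    "tokenize",
]

#: Default report separator: a line consisting solely of this marker.
DEFAULT_DELIMITER = r"^=====END_OF_REPORT=====\s*$"

#: Common subjective-section titles; these start sections but are searched.
DEFAULT_SUBJECTIVE_HEADINGS = frozenset(
    {
        "chief complaint",
        "history of present illness",
        "hpi",
        "past medical history",
        "pmh",
        "past surgical history",
        "social history",
        "review of systems",
        "medications",
        "allergies",
        "hospital course",
    }
)

_EDGE_PUNCT = "\"'`.,;:!?()[]{}<>*-_/\\"
_ID_LINE = re.compile(r"^REPORT_ID:\s*(\S+)\s*$")


@dataclass(frozen=True)
class TokenSpan:
    """One whitespace-delimited token with its position in the sentence."""

    raw: str          # original text, punctuation included
    norm: str         # lowercase, edge punctuation stripped
    start: int        # character offset into sentence text (0-based)
    end: int          # half-open end offset

    @property
    def stripped(self) -> str:
        """Edge-punctuation-stripped raw token, case preserved (acronym check)."""
        return self.raw.strip(_EDGE_PUNCT)


@dataclass(frozen=True)
class Sentence:
    text: str
    tokens: tuple[TokenSpan, ...]

    @property
    def norms(self) -> tuple[str, ...]:
        return tuple(t.norm for t in self.tokens)


@dataclass
class Section:
    heading: str | None                 # None for the heading-less preamble
    heading_line: str | None
    is_family_history: bool
    is_subjective: bool
    text: str = ""
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def location(self) -> str:
        return self.heading if self.heading is not None else "preamble"


@dataclass
class Report:
    report_id: str
    raw_text: str
    sections: list[Section] = field(default_factory=list)

    def subjective_sentences(self) -> Iterable[tuple[Section, Sentence]]:
        for section in self.sections:
            if section.is_subjective:
                for sentence in section.sentences:
                    yield section, sentence


def tokenize(text: str) -> tuple[TokenSpan, ...]:
    """Whitespace tokenization with lowercase, edge-punctuation-stripped norms.

    Tokens whose norm is empty (pure punctuation) are dropped.  Internal
    punctuation such as hyphens is preserved ("T-PLL," -> norm "t-pll").
    """
    spans = []
    for match in re.finditer(r"\S+", text):
        raw = match.group(0)
        norm = raw.strip(_EDGE_PUNCT).lower()
        if norm:
            spans.append(TokenSpan(raw, norm, match.start(), match.end()))
    return tuple(spans)


def _split_line_sentences(line: str) -> list[str]:
    """Split one physical line at terminal punctuation before a capital/digit."""
    pieces = re.split(r"(?<=[.!?])\s+(?=[A-Z0-9])", line)
    return [p for p in pieces if p.strip()]


def split_sentences(text: str) -> list[Sentence]:
    """Sentence segmentation for section text.

    Sentences end at ``.``/``!``/``?`` followed by whitespace and a capital
    letter or digit, or at the end of a line.  Treating every hard line break
    as a boundary keeps run-on, unpunctuated report sections from collapsing
    into one giant sentence (a documented failure mode of naive splitters on
    transcribed notes).
    """
    sentences = []
    for line in text.splitlines():
        for piece in _split_line_sentences(line):
            sentences.append(Sentence(piece, tokenize(piece)))
    return sentences


def _normalize_heading(text: str) -> str:
    return " ".join(text.split()).rstrip(":").strip().lower()


def _heading_sets(lex: Lexicon, subjective_headings: Iterable[str]):
    family = {_normalize_heading(h) for h in lex.family_history_headings}
    nonsubjective = {_normalize_heading(h) for h in lex.nonsubjective_headings}
    subjective = {_normalize_heading(h) for h in subjective_headings}
    return family, nonsubjective, family | nonsubjective | subjective


def _match_heading(line: str, known: set[str]) -> tuple[str, str] | None:
    """Return (heading text, trailing content) if the line opens a section.

    A heading is the text before the first colon (at most 60 characters), or
    the whole line when it has no colon, matched case-insensitively against
    the known heading inventory.
    """
    stripped = line.strip()
    if not stripped:
        return None
    if ":" in stripped:
        head, _, rest = stripped.partition(":")
        if len(head) <= 60 and _normalize_heading(head) in known:
            return head.strip(), rest.strip()
    if len(stripped) <= 60 and _normalize_heading(stripped) in known:
        return stripped, ""
    return None


def segment_sections(
    report: Report,
    lex: Lexicon | None = None,
    subjective_headings: Iterable[str] = DEFAULT_SUBJECTIVE_HEADINGS,
) -> Report:
    """Populate ``report.sections`` (and their sentences) from ``raw_text``.

    A new section starts at each line whose leading text matches a known
    heading (family-history, non-subjective, or subjective inventory); text
    before the first heading becomes a heading-less preamble, which is
    treated as subjective.
    """
    lex = lex or default_lexicon()
    family, nonsubjective, known = _heading_sets(lex, subjective_headings)

    sections: list[Section] = []
    current = Section(None, None, False, True)

    def flush():
        if current.heading is not None or current.text.strip():
            current.sentences = split_sentences(current.text)
            sections.append(current)

    for line in report.raw_text.splitlines():
        matched = _match_heading(line, known)
        if matched is not None:
            flush()
            head, rest = matched
            norm = _normalize_heading(head)
            # keep inline content out of heading_line so that heading_line +
            # text reconstructs the raw line up to whitespace
            current = Section(
                heading=head,
                heading_line=f"{head}:" if rest else line,
                is_family_history=norm in family,
                is_subjective=norm not in nonsubjective,
                text=rest + "\n" if rest else "",
            )
        else:
            current.text += line + "\n"
    flush()

    report.sections = sections
    return report


def split_corpus(
    text: str, delimiter: str = DEFAULT_DELIMITER
) -> list[Report]:
    """Split corpus text into :class:`Report` objects (sections unparsed).

    One report per delimiter-separated block, in order.  A leading
    ``REPORT_ID: <id>`` line names the report; otherwise sequential 1-based
    ids are assigned.  Empty blocks are skipped with a warning.
    """
    if not text.strip():
        raise ValueError("corpus text is empty")
    pattern = re.compile(delimiter, re.MULTILINE)
    blocks = pattern.split(text)

    reports = []
    counter = 0
    for block in blocks:
        if not block.strip():
            if block is not blocks[-1]:
                warnings.warn("skipping empty report block", stacklevel=2)
            continue
        counter += 1
        lines = block.strip("\n").splitlines()
        report_id = str(counter)
        body_lines = lines
        for i, line in enumerate(lines):
            if not line.strip():
                continue
            match = _ID_LINE.match(line.strip())
            if match:
                report_id = match.group(1)
                body_lines = lines[:i] + lines[i + 1 :]
            break
        reports.append(Report(report_id, "\n".join(body_lines)))
    return reports


def parse_report(
    report: Report,
    lex: Lexicon | None = None,
    subjective_headings: Iterable[str] = DEFAULT_SUBJECTIVE_HEADINGS,
) -> Report:
    return segment_sections(report, lex, subjective_headings)


def parse_corpus(
    text: str,
    lex: Lexicon | None = None,
    delimiter: str = DEFAULT_DELIMITER,
    subjective_headings: Iterable[str] = DEFAULT_SUBJECTIVE_HEADINGS,
) -> list[Report]:
    """Full structural parse: split into reports, sections and sentences."""
    lex = lex or default_lexicon()
    reports = split_corpus(text, delimiter)
    for report in reports:
        segment_sections(report, lex, subjective_headings)
    return reports
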