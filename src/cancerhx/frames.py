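"""The seven-slot semantic cancer frame shared by both frame builders.

A frame records one cancer-concept mention: which report it came from, the
located cancer term, any modifier phrases, who experiences the cancer
(patient, a specific relative, or "unknown family"), any matched negation
phrases, the section it was found in, and the raw sentence text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "EXPERIENCER_PATIENT",
    "EXPERIENCER_UNKNOWN_FAMILY",
    "CancerFrame",
    "FrameLabel",
    "full_phrase",
    "dump_frames",
    "load_frames",
]

EXPERIENCER_PATIENT = "patient"
EXPERIENCER_UNKNOWN_FAMILY = "unknown_family"

_COLUMNS = (
    "report_id",
    "cancer_term",
    "modifiers",
    "experiencer",
    "negation_terms",
    "section_location",
    "sentence_text",
)
_LIST_SEP = "|"


@dataclass(frozen=True)
class CancerFrame:
    """One cancer-concept mention with its seven extracted slots."""

    report_id: str
    cancer_term: str
    modifiers: tuple[str, ...]
    experiencer: str
    negation_terms: tuple[str, ...]
    section_location: str
    sentence_text: str

    def __post_init__(self):
        for slot in ("report_id", "cancer_term", "section_location", "sentence_text"):
            if not getattr(self, slot):
                raise ValueError(f"frame slot {slot!r} must be non-empty")

    @property
    def is_negated(self) -> bool:
        return bool(self.negation_terms)

    @property
    def is_family(self) -> bool:
        return self.experiencer != EXPERIENCER_PATIENT


def full_phrase(frame: CancerFrame) -> str:
    """Unified concept phrase: modifiers (in text order) then the cancer term.

    ``modifiers ["small cell", "lung"], term "cancer"`` -> ``"small cell lung
    cancer"``; with no modifiers the phrase is the term itself.
    """
    return " ".join((*frame.modifiers, frame.cancer_term))


@dataclass(frozen=True)
class FrameLabel:
    """Derived per-frame view used by report classification."""

    is_negated: bool
    is_family: bool
    is_mesothelioma: bool
    resolved_cancer: str

    @classmethod
    def from_frame(cls, frame: CancerFrame, resolved: str | None = None):
        resolved = resolved if resolved is not None else full_phrase(frame)
        return cls(
            is_negated=frame.is_negated,
            is_family=frame.is_family,
            is_mesothelioma="mesothelioma" in resolved.lower().split(),
            resolved_cancer=resolved,
        )


def dump_frames(frames: Iterable[CancerFrame]) -> str:
    """Tab-separated frame dump: header plus one frame per line.

    List slots (modifiers, negation terms) are joined with ``|``; tabs and
    newlines inside sentence text are flattened to spaces.
    """
    out = io.StringIO()
    out.write("\t".join(_COLUMNS) + "\n")
    for frame in frames:
        row = (
            frame.report_id,
            frame.cancer_term,
            _LIST_SEP.join(frame.modifiers),
            frame.experiencer,
            _LIST_SEP.join(frame.negation_terms),
            frame.section_location,
            " ".join(frame.sentence_text.split()),
        )
        out.write("\t".join(row) + "\n")
    return out.getvalue()


def load_frames(text: str) -> list[CancerFrame]:
    """Inverse of :func:`dump_frames`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != list(_COLUMNS):
        raise ValueError("frame dump missing expected header")
    frames = []
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(_COLUMNS):
            raise ValueError(f"malformed frame row: {line!r}")
        rid, term, mods, exp, negs, section, sentence = cells
        frames.append(
            CancerFrame(
                report_id=rid,
                cancer_term=term,
                modifiers=tuple(m for m in mods.split(_LIST_SEP) if m),
                experiencer=exp,
                negation_terms=tuple(n for n in negs.split(_LIST_SEP) if n),
                section_location=section,
                sentence_text=sentence,
            )
        )
    return frames
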