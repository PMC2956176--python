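"""Frame evaluation: reference resolution and per-report Q1/Q2 verdicts.

Two report-level questions are answered from the frames:

Q1 — does the patient have a personal history of *ancillary* cancer (any
malignancy other than the known mesothelioma)?  Patient-experienced,
non-negated frames count, except those whose (resolved) cancer identity is
mesothelioma: the patient population is mesothelioma patients, so the known
cancer never counts as ancillary.

Q2 — is there a family history of *any* cancer (mesothelioma included)?
Any non-negated frame experienced by a family member counts.

Generic mentions ("the cancer", "tumor" with no modifiers) carry no cancer
identity of their own; reference resolution scans the report's earlier
frames in reverse for the nearest *specified* frame and adopts its phrase,
defaulting to mesothelioma when none exists — in this population an
unanchored generic mention most plausibly refers to the known disease.
Reports are classified independently; no state crosses report boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .frames import EXPERIENCER_PATIENT, CancerFrame, full_phrase

__all__ = [
    "CorpusSummary",
    "ReportClassification",
    "classify_q1",
    "classify_q2",
    "classify_report",
    "is_specified",
    "resolve_reference",
    "summarize",
]

#: Generic cancer words that carry no identity without modifiers.
_GENERIC_TERMS = frozenset({"cancer", "tumor", "neoplasm"})

_MESO = "mesothelioma"


def is_specified(frame: CancerFrame) -> bool:
    """False iff the frame captured only a bare generic term.

    "adenocarcinoma" and "lung cancer" are specified; a bare "cancer",
    "tumor" or "neoplasm" with no modifiers is not.
    """
    return not (frame.cancer_term.lower() in _GENERIC_TERMS and not frame.modifiers)


def resolve_reference(
    frame: CancerFrame, prior_frames: Sequence[CancerFrame]
) -> str:
    """Resolve an unspecified frame against earlier frames of the report.

    Scans ``prior_frames`` (document order) in reverse for the nearest
    specified frame and returns its full phrase; with no specified
    antecedent the mention is taken to be the known mesothelioma.
    """
    if is_specified(frame):
        raise ValueError("resolve_reference called on a specified frame")
    for prior in reversed(prior_frames):
        if is_specified(prior):
            return full_phrase(prior)
    return _MESO


def _resolved_phrase(frame: CancerFrame, prior: Sequence[CancerFrame]) -> str:
    return full_phrase(frame) if is_specified(frame) else resolve_reference(frame, prior)


def _is_mesothelioma_phrase(phrase: str) -> bool:
    # Modifier variants ("malignant mesothelioma") still count as the known cancer.
    return _MESO in phrase.lower().split()


def classify_q1(frames: Sequence[CancerFrame]) -> tuple[bool, list[CancerFrame]]:
    """Personal history of ancillary cancer, with supporting frames."""
    supporting = []
    for i, frame in enumerate(frames):
        if frame.experiencer != EXPERIENCER_PATIENT or frame.is_negated:
            continue
        if _is_mesothelioma_phrase(_resolved_phrase(frame, frames[:i])):
            continue
        supporting.append(frame)
    return bool(supporting), supporting


def classify_q2(frames: Sequence[CancerFrame]) -> tuple[bool, list[CancerFrame]]:
    """Family history of any cancer (mesothelioma counts), with support."""
    supporting = [
        frame
        for frame in frames
        if frame.experiencer != EXPERIENCER_PATIENT and not frame.is_negated
    ]
    return bool(supporting), supporting


@dataclass
class ReportClassification:
    report_id: str
    q1_personal_ancillary: bool
    q2_family_any: bool
    q1_supporting: list[CancerFrame] = field(default_factory=list)
    q2_supporting: list[CancerFrame] = field(default_factory=list)


def classify_report(
    report_id: str, frames: Sequence[CancerFrame]
) -> ReportClassification:
    """Answer both questions for one report's frames (document order)."""
    q1, q1_support = classify_q1(frames)
    q2, q2_support = classify_q2(frames)
    return ReportClassification(report_id, q1, q2, q1_support, q2_support)


def _id_key(report_id: str):
    return (0, int(report_id), "") if report_id.isdigit() else (1, 0, report_id)


@dataclass
class CorpusSummary:
    n_reports: int
    q1_positive_ids: list[str]
    q2_positive_ids: list[str]

    @property
    def q1_count(self) -> int:
        return len(self.q1_positive_ids)

    @property
    def q2_count(self) -> int:
        return len(self.q2_positive_ids)

    def format(self) -> str:
        lines = [
            f"Reports classified: {self.n_reports}",
            f"Q1 positive (personal history of ancillary cancer): {self.q1_count}",
            *(f"  {rid}" for rid in self.q1_positive_ids),
            f"Q2 positive (family history of any cancer): {self.q2_count}",
            *(f"  {rid}" for rid in self.q2_positive_ids),
        ]
        return "\n".join(lines)


def summarize(classifications: Sequence[ReportClassification]) -> CorpusSummary:
    """Corpus-level summary: positive report ids per question, stably ordered."""
    q1 = sorted(
        (c.report_id for c in classifications if c.q1_personal_ancillary), key=_id_key
    )
    q2 = sorted(
        (c.report_id for c in classifications if c.q2_family_any), key=_id_key
    )
    return CorpusSummary(len(classifications), q1, q2)
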