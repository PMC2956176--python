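"""End-to-end convenience layer: parse -> build frames -> classify."""

from __future__ import annotations

from typing import Sequence

from .context_method import build_frames_context
from .dynamic_window import WindowConfig, build_frames_dynamic_window
from .evaluation import ReportClassification, classify_report
from .frames import CancerFrame
from .lexicon import Lexicon, default_lexicon
from .parsing import DEFAULT_DELIMITER, Report, parse_corpus

__all__ = ["ENGINES", "build_frames", "classify_corpus", "classify_text"]

ENGINES = ("dynamic-window", "context")


def build_frames(
    report: Report,
    engine: str = "dynamic-window",
    lex: Lexicon | None = None,
    cfg: WindowConfig | None = None,
    modifier_scope: str = "sentence",
) -> list[CancerFrame]:
    """Build frames for one parsed report with the selected engine."""
    if engine in ("dynamic-window", "dynamic_window"):
        return build_frames_dynamic_window(report, lex, cfg)
    if engine == "context":
        return build_frames_context(report, lex, modifier_scope, cfg)
    raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")


def classify_text(
    text: str,
    engine: str = "dynamic-window",
    lex: Lexicon | None = None,
    cfg: WindowConfig | None = None,
    modifier_scope: str = "sentence",
    delimiter: str = DEFAULT_DELIMITER,
) -> tuple[list[ReportClassification], list[CancerFrame]]:
    """Classify every report in a corpus string.

    Returns per-report classifications (corpus order) and all frames built.
    """
    lex = lex or default_lexicon()
    reports = parse_corpus(text, lex, delimiter)
    return classify_corpus(reports, engine, lex, cfg, modifier_scope)


def classify_corpus(
    reports: Sequence[Report],
    engine: str = "dynamic-window",
    lex: Lexicon | None = None,
    cfg: WindowConfig | None = None,
    modifier_scope: str = "sentence",
) -> tuple[list[ReportClassification], list[CancerFrame]]:
    classifications = []
    all_frames = []
    for report in reports:
        frames = build_frames(report, engine, lex, cfg, modifier_scope)
        classifications.append(classify_report(report.report_id, frames))
        all_frames.extend(frames)
    return classifications, all_frames
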