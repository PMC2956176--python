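"""Domain lexicon: load, validate and query the five-group term store.

The lexicon drives every matching step in the pipeline: cancer-concept
identification (non-cancer ``-oma`` words, acronyms, unique cancer words),
modifier descriptors and "cancer-as-adjective" nouns, kinship terms, report
section headings, and negation phrases.  It is organised as eleven named
categories; a packaged default transcribes the published term inventory and
user configs may extend or override it per category.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "CATEGORIES",
    "Lexicon",
    "LexiconError",
    "default_lexicon",
    "extend_lexicon",
    "load_lexicon",
    "phrase_in",
    "segment_modifiers",
    "segmentable_as_modifiers",
]

#: The eleven recognised category names, in declaration order.
CATEGORIES = (
    "noncancer_oma_terms",
    "cancer_acronyms",
    "unique_cancers",
    "modifier_descriptors",
    "cancer_as_adjective_nouns",
    "kinship_fdr",
    "kinship_other",
    "nonrelatives",
    "family_history_headings",
    "nonsubjective_headings",
    "negation_phrases",
)

#: Category pairs that must never share an entry.
_EXCLUSIVE_PAIRS = (
    ("kinship_fdr", "nonrelatives"),
    ("kinship_other", "nonrelatives"),
    ("kinship_fdr", "kinship_other"),
    ("modifier_descriptors", "negation_phrases"),
)


class LexiconError(ValueError):
    """Malformed or inconsistent lexicon configuration."""


@dataclass(frozen=True)
class Lexicon:
    """Validated, immutable term store.

    All entries except ``cancer_acronyms`` are stored lowercase; acronyms keep
    their original case and are matched case-sensitively against raw tokens.
    """

    noncancer_oma_terms: frozenset[str]
    cancer_acronyms: frozenset[str]
    unique_cancers: frozenset[str]
    modifier_descriptors: frozenset[str]
    cancer_as_adjective_nouns: frozenset[str]
    kinship_fdr: frozenset[str]
    kinship_other: frozenset[str]
    nonrelatives: frozenset[str]
    family_history_headings: frozenset[str]
    nonsubjective_headings: frozenset[str]
    negation_phrases: frozenset[str]

    def category(self, name: str) -> frozenset[str]:
        if name not in CATEGORIES:
            raise LexiconError(f"unknown lexicon category: {name!r}")
        return getattr(self, name)

    @property
    def max_descriptor_len(self) -> int:
        """Longest modifier-descriptor phrase, in tokens."""
        return max((len(p.split()) for p in self.modifier_descriptors), default=0)

    @property
    def max_negation_len(self) -> int:
        return max((len(p.split()) for p in self.negation_phrases), default=0)

    def to_dict(self) -> dict[str, list[str]]:
        """Serializable mapping with sorted entry lists (round-trip safe)."""
        return {name: sorted(getattr(self, name)) for name in CATEGORIES}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)


def _normalize(category: str, entries: Iterable[str]) -> frozenset[str]:
    out = set()
    for raw in entries:
        if not isinstance(raw, str):
            raise LexiconError(
                f"category {category!r}: entries must be strings, got {raw!r}"
            )
        term = " ".join(raw.split())
        if not term:
            raise LexiconError(f"category {category!r}: empty entry")
        if category != "cancer_acronyms":
            term = term.lower()
        out.add(term)
    return frozenset(out)


def _validate(lex: Lexicon) -> Lexicon:
    for left, right in _EXCLUSIVE_PAIRS:
        clash = lex.category(left) & lex.category(right)
        if clash:
            raise LexiconError(
                f"entries {sorted(clash)} appear in mutually exclusive "
                f"categories {left!r} and {right!r}"
            )
    return lex


def load_lexicon(source: str | Path | Mapping[str, Iterable[str]]) -> Lexicon:
    """Load a lexicon from YAML text, a YAML file path, or a mapping.

    The config must declare all eleven categories (empty lists allowed);
    unknown categories are rejected.  Raises :class:`LexiconError` on
    malformed input or mutually exclusive duplicate entries.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        text = source
        if isinstance(source, Path) or (
            "\n" not in str(source) and Path(str(source)).is_file()
        ):
            text = Path(source).read_text(encoding="utf-8")
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
            raise LexiconError(f"could not parse lexicon config: {exc}") from exc
        if not isinstance(data, Mapping):
            raise LexiconError("lexicon config must be a mapping of categories")

    unknown = set(data) - set(CATEGORIES)
    if unknown:
        raise LexiconError(f"unknown lexicon categories: {sorted(unknown)}")
    missing = set(CATEGORIES) - set(data)
    if missing:
        raise LexiconError(f"missing lexicon categories: {sorted(missing)}")

    kwargs = {
        name: _normalize(name, data[name] if data[name] is not None else [])
        for name in CATEGORIES
    }
    return _validate(Lexicon(**kwargs))


_DEFAULT: Lexicon | None = None


def default_lexicon() -> Lexicon:
    """The packaged default lexicon (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = (
            importlib.resources.files("cancerhx.data")
            .joinpath("default_lexicon.yaml")
            .read_text(encoding="utf-8")
        )
        _DEFAULT = load_lexicon(text)
    return _DEFAULT


def extend_lexicon(base: Lexicon, extra: Mapping[str, Iterable[str]]) -> Lexicon:
    """Return ``base`` with extra entries merged into the named categories."""
    unknown = set(extra) - set(CATEGORIES)
    if unknown:
        raise LexiconError(f"unknown lexicon categories: {sorted(unknown)}")
    changes = {
        name: base.category(name) | _normalize(name, terms)
        for name, terms in extra.items()
    }
    return _validate(replace(base, **changes))


def phrase_in(lex: Lexicon, category: str, tokens: Sequence[str]) -> bool:
    """True iff ``tokens`` joined on single spaces is a member of ``category``.

    Case-insensitive for every category except ``cancer_acronyms``, which is
    matched exact-case against the raw (pre-lowercasing) token text.
    """
    members = lex.category(category)
    if not tokens:
        return False
    joined = " ".join(tokens)
    if category == "cancer_acronyms":
        return joined in members
    return joined.lower() in members


def segment_modifiers(
    tokens: Sequence[str], lex: Lexicon
) -> list[str] | None:
    """Partition ``tokens`` into contiguous modifier-descriptor phrases.

    Returns the phrase list (leftmost-longest backtrack) if the whole token
    sequence is exactly partitionable into ``modifier_descriptors`` entries
    with no leftover tokens, else ``None``.  Dynamic programming over prefix
    feasibility; descriptor phrases are at most :attr:`Lexicon.max_descriptor_len`
    tokens long.
    """
    if not tokens:
        return None
    norms = [t.lower() for t in tokens]
    n = len(norms)
    maxlen = lex.max_descriptor_len
    descriptors = lex.modifier_descriptors

    # ok[j] == True iff norms[j:] is fully segmentable.
    ok = [False] * (n + 1)
    ok[n] = True
    for j in range(n - 1, -1, -1):
        for length in range(1, min(maxlen, n - j) + 1):
            if ok[j + length] and " ".join(norms[j : j + length]) in descriptors:
                ok[j] = True
                break
    if not ok[0]:
        return None

    phrases: list[str] = []
    j = 0
    while j < n:
        for length in range(min(maxlen, n - j), 0, -1):
            candidate = " ".join(norms[j : j + length])
            if candidate in descriptors and ok[j + length]:
                phrases.append(candidate)
                j += length
                break
    return phrases


def segmentable_as_modifiers(tokens: Sequence[str], lex: Lexicon) -> bool:
    """True iff ``tokens`` partitions exactly into descriptor phrases."""
    return segment_modifiers(tokens, lex) is not None
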