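"""Seeded generator of H&P-style report corpora with known ground truth.

Real mesothelioma H&P reports are PHI-restricted, so testing runs on
synthetic corpora that emulate their structure: section-headed narrative
(chief complaint, HPI, past medical history, family history, physical exam,
assessment), cancer mentions with and without modifiers, negation phrases at
controlled token distances, kinship attributions, mesothelioma vs ancillary
cancer mentions, and decoy constructs ("tumor markers", "cancer conference",
"hematoma").

Every planted sentence comes from a fixed *pattern inventory*; each pattern
declares its gold-label contribution and the outcome each engine is expected
to produce on it, so corpora double as behavioural oracles:

* ``easy`` corpora use only patterns both engines handle correctly — either
  engine must reproduce the gold labels exactly;
* ``documented_limitations`` corpora additionally plant the known hard
  sentences (negation pushed beyond the five-token window reach, the
  sentence-wide modifier trap, either/or constructions), on which each
  engine errs in a predictable, pattern-specific way;
* ``mixed`` blends the two.

Default prevalences mirror the study population: 20% of reports carry a
personal history of ancillary cancer and 27% note a family history of
cancer.  All sampling flows through one ``random.Random`` stream keyed by
the seed, so generation is byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

__all__ = [
    "GoldRecord",
    "Pattern",
    "SynthSpec",
    "expected_labels",
    "generate_corpus",
    "pattern_inventory",
    "read_gold",
    "write_gold",
]

DELIMITER_LINE = "=====END_OF_REPORT====="

# Safe vocabulary pools: every entry is a single-token modifier descriptor
# from the default lexicon, so windowed and sentence-wide matching agree.
_DESCRIPTORS = (
    "breast", "colon", "prostate", "bladder", "ovarian",
    "thyroid", "skin", "pancreatic", "gastric", "rectal",
)
_ORGANS = ("bladder", "colon", "prostate", "skin", "stomach")
_ACRONYMS = ("SCLC", "CLL", "AML", "HCC")
_KIN_FDR = ("mother", "father", "sister", "brother")
_KIN_OTHER = ("uncle", "aunt", "grandmother", "grandfather")

# The documented hard sentences, planted verbatim.
SENTENCE_NEG_OUT_OF_REACH = "There is no family history of diabetes or cancer."
SENTENCE_MODIFIER_TRAP = (
    "The patient underwent tumor debulking with chemoperfusion, splenectomy, "
    "omentectomy and interoperative ultrasound of the liver."
)
SENTENCE_EITHER_OR = (
    "The pathology was consistent with either mesothelioma versus "
    "signet-ring cell adenocarcinoma."
)


@dataclass(frozen=True)
class Pattern:
    """One sentence template with declared gold and per-engine behaviour.

    ``gold``, ``dynamic_window`` and ``context`` are (q1, q2) report-label
    contributions; a report's expected label is the OR over its planted
    patterns.  ``fh_only_partner`` marks patterns that must not share a
    report with cancer frames earlier than themselves (they rely on
    reference resolution falling back to mesothelioma), so any family
    pattern in that report is forced into the later family-history section.
    """

    pattern_id: str
    slot: str                      # "q1" | "q2" | "decoy"
    section: str                   # "hpi" | "pmh" | "fh" | "pe"
    hardness: str                  # "easy" | "hard"
    gold: tuple[bool, bool]
    dynamic_window: tuple[bool, bool]
    context: tuple[bool, bool]
    render: Callable[[random.Random], str]
    fh_only_partner: bool = False


def _p(rng: random.Random, pool: Sequence[str]) -> str:
    return rng.choice(pool)


def _year(rng: random.Random) -> int:
    return rng.randint(1985, 2006)


_NEGATED_TEMPLATES = (
    # negation at controlled distances from the hot-spot (1-4 tokens after
    # dynamic expansion; the raw distance runs up to 6 with stacked modifiers)
    "She has had no {d} cancer.",
    "The patient has no history of {d} cancer.",
    "The patient denies any history of {d} cancer.",
    "The patient is without a history of {d} cancer.",
    "The patient has no history of small cell lung cancer in her record.",
)


def _inventory() -> dict[str, Pattern]:
    neg = (False, False)
    patterns = [
        # --- Q1 slot: personal ancillary cancer -------------------------
        Pattern(
            "q1_specified", "q1", "pmh", "easy",
            (True, False), (True, False), (True, False),
            lambda rng: (
                f"The patient was diagnosed with {_p(rng, _DESCRIPTORS)} "
                f"cancer in {_year(rng)}."
            ),
        ),
        Pattern(
            "q1_oma_forward", "q1", "hpi", "easy",
            (True, False), (True, False), (True, False),
            lambda rng: (
                f"Pathology confirmed adenocarcinoma of the {_p(rng, _ORGANS)}."
            ),
        ),
        Pattern(
            "q1_acronym", "q1", "pmh", "easy",
            (True, False), (True, False), (True, False),
            lambda rng: f"Past history is significant for {_p(rng, _ACRONYMS)}.",
        ),
        Pattern(
            "q1_forward_location", "q1", "hpi", "easy",
            (True, False), (True, False), (True, False),
            lambda rng: f"The patient has cancer of the {_p(rng, _ORGANS)}.",
        ),
        Pattern(
            "q1_negated", "q1", "pmh", "easy", neg, neg, neg,
            lambda rng: rng.choice(_NEGATED_TEMPLATES).format(
                d=_p(rng, _DESCRIPTORS)
            ),
        ),
        Pattern(
            "q1_meso_mention", "q1", "hpi", "easy", neg, neg, neg,
            lambda rng: "The patient carries a diagnosis of malignant mesothelioma.",
        ),
        Pattern(
            "q1_generic_reference", "q1", "hpi", "easy", neg, neg, neg,
            lambda rng: "The cancer was excised 6 months ago.",
            fh_only_partner=True,
        ),
        Pattern(
            "sentencewide_modifier_trap", "q1", "hpi", "hard",
            neg, neg, (True, False),
            lambda rng: SENTENCE_MODIFIER_TRAP,
            fh_only_partner=True,
        ),
        Pattern(
            "either_or", "q1", "hpi", "hard",
            neg, (True, False), (True, False),
            lambda rng: SENTENCE_EITHER_OR,
        ),
        # --- Q2 slot: family history ------------------------------------
        Pattern(
            "q2_kinship_fh", "q2", "fh", "easy",
            (False, True), (False, True), (False, True),
            lambda rng: (
                f"{_p(rng, _KIN_FDR).capitalize()} had "
                f"{_p(rng, _DESCRIPTORS)} cancer at age {rng.randint(48, 85)}."
            ),
        ),
        Pattern(
            "q2_kinship_hpi", "q2", "hpi", "easy",
            (False, True), (False, True), (False, True),
            lambda rng: (
                f"Her {_p(rng, _KIN_FDR + _KIN_OTHER)} was treated for "
                f"{_p(rng, _DESCRIPTORS)} cancer."
            ),
        ),
        Pattern(
            "q2_unknown_family", "q2", "fh", "easy",
            (False, True), (False, True), (False, True),
            lambda rng: rng.choice(
                (
                    "There is a family history of leukemia.",
                    "There is a family history of cancer on the maternal side.",
                )
            ),
        ),
        Pattern(
            "q2_meso_family", "q2", "fh", "easy",
            (False, True), (False, True), (False, True),
            lambda rng: f"{_p(rng, _KIN_FDR).capitalize()} died of mesothelioma.",
        ),
        Pattern(
            "q2_negated_fh", "q2", "fh", "easy", neg, neg, neg,
            lambda rng: "No family history of cancer.",
        ),
        Pattern(
            "q2_nonrelative", "q2", "hpi", "easy", neg, neg, neg,
            lambda rng: (
                f"Her husband was treated for {_p(rng, _DESCRIPTORS)} "
                "cancer last year."
            ),
        ),
        Pattern(
            "q2_noncontributory", "q2", "fh", "easy", neg, neg, neg,
            lambda rng: "Noncontributory.",
        ),
        Pattern(
            "neg_distance_6", "q2", "fh", "hard",
            neg, (False, True), neg,
            lambda rng: SENTENCE_NEG_OUT_OF_REACH,
        ),
        # --- decoys ------------------------------------------------------
        Pattern(
            "decoy_tumor_markers", "decoy", "pmh", "easy", neg, neg, neg,
            lambda rng: "Tumor markers were within normal limits.",
        ),
        Pattern(
            "decoy_hematoma", "decoy", "hpi", "easy", neg, neg, neg,
            lambda rng: "There is a resolving hematoma on the left thigh.",
        ),
        Pattern(
            "decoy_cancer_conference", "decoy", "hpi", "easy", neg, neg, neg,
            lambda rng: "Her case was reviewed at the cancer conference last week.",
        ),
        Pattern(
            "decoy_run_on", "decoy", "hpi", "easy", neg, neg, neg,
            lambda rng: (
                "Patient reports increasing shortness of breath\n"
                "Appetite has been poor over the past month\n"
                "Sleep has been adequate"
            ),
        ),
        Pattern(
            "objective_trap", "decoy", "pe", "easy", neg, neg, neg,
            lambda rng: "There is a firm mass suspicious for carcinoma.",
        ),
    ]
    return {p.pattern_id: p for p in patterns}


_INVENTORY = _inventory()


def pattern_inventory() -> dict[str, Pattern]:
    """The full pattern catalogue, keyed by pattern id."""
    return dict(_INVENTORY)


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters (defaults mirror the study prevalences)."""

    n_reports: int
    q1_prevalence: float = 0.20
    q2_prevalence: float = 0.27
    construct_mix: Mapping[str, float] | None = None
    hardness: str = "easy"
    seed: int = 0

    def __post_init__(self):
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        for name in ("q1_prevalence", "q2_prevalence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hardness not in ("easy", "documented_limitations", "mixed"):
            raise ValueError(f"unknown hardness {self.hardness!r}")
        if self.construct_mix is not None:
            unknown = set(self.construct_mix) - set(_INVENTORY)
            if unknown:
                raise ValueError(f"unknown pattern ids in construct_mix: "
                                 f"{sorted(unknown)}")
            if any(w < 0 for w in self.construct_mix.values()):
                raise ValueError("construct_mix weights must be non-negative")


@dataclass(frozen=True)
class GoldRecord:
    report_id: str
    q1: bool
    q2: bool
    planted_constructs: tuple[str, ...]


def expected_labels(record: GoldRecord, engine: str) -> tuple[bool, bool]:
    """The (q1, q2) labels an engine is expected to produce for a report."""
    attr = {"dynamic-window": "dynamic_window", "dynamic_window": "dynamic_window",
            "context": "context"}.get(engine)
    if attr is None:
        raise ValueError(f"unknown engine {engine!r}")
    q1 = q2 = False
    for pid in record.planted_constructs:
        contrib = getattr(_INVENTORY[pid], attr)
        q1 = q1 or contrib[0]
        q2 = q2 or contrib[1]
    return q1, q2


def _pool(slot: str, positive: bool, hardness: str, mix) -> list[Pattern]:
    """Candidate patterns for a slot outcome under the hardness regime."""
    out = []
    for pattern in _INVENTORY.values():
        if pattern.slot != slot:
            continue
        if (pattern.gold[0] or pattern.gold[1]) != positive:
            continue
        if hardness == "easy" and pattern.hardness == "hard":
            continue
        if mix is not None and mix.get(pattern.pattern_id, 1.0) == 0:
            continue
        out.append(pattern)
    return out


def _weighted_choice(rng: random.Random, pool: Sequence[Pattern],
                     mix, hard_boost: float) -> Pattern:
    weights = []
    for pattern in pool:
        w = 1.0 if mix is None else mix.get(pattern.pattern_id, 1.0)
        if pattern.hardness == "hard":
            w *= hard_boost
        weights.append(w)
    return rng.choices(pool, weights=weights, k=1)[0]


_HPI_FILLER = (
    "{Pron} presented today for follow-up of {pron_poss} mesothelioma.",
    "{Pron} reports mild dyspnea on exertion.",
    "Pain is well controlled on the current regimen.",
    "{Pron} denies fevers, chills, or night sweats.",
)
_PMH_FILLER = ("Hypertension and hyperlipidemia.", "Type 2 diabetes mellitus.",
               "Gastroesophageal reflux disease.")
_CC_FILLER = ("Shortness of breath.", "Chest discomfort.", "Follow-up visit.")
_PE_FILLER = ("Lungs with decreased breath sounds at the right base.",
              "Abdomen soft and nontender.")
_ASSESS_FILLER = ("Malignant mesothelioma, currently stable.",
                  "Continue current management.")


def _render_report(rng: random.Random, report_id: str, age: int, sex: str,
                   patterns: Sequence[Pattern]) -> str:
    pron = "He" if sex == "man" else "She"
    poss = "his" if sex == "man" else "her"
    by_section: dict[str, list[str]] = {"hpi": [], "pmh": [], "fh": [], "pe": []}
    for pattern in patterns:
        by_section[pattern.section].append(pattern.render(rng))

    hpi = [
        f"The patient is a {age}-year-old {sex} with known mesothelioma.",
        rng.choice(_HPI_FILLER).format(Pron=pron, pron_poss=poss),
        *by_section["hpi"],
    ]
    pmh = [rng.choice(_PMH_FILLER), *by_section["pmh"]]
    fh = by_section["fh"] or ["Noncontributory."]
    pe = [rng.choice(_PE_FILLER), *by_section["pe"]]

    lines = [
        f"REPORT_ID: {report_id}",
        f"CHIEF COMPLAINT: {rng.choice(_CC_FILLER)}",
        "HISTORY OF PRESENT ILLNESS:",
        *hpi,
        "PAST MEDICAL HISTORY:",
        *pmh,
        "FAMILY HISTORY:",
        *fh,
        "PHYSICAL EXAMINATION:",
        *pe,
        "ASSESSMENT:",
        rng.choice(_ASSESS_FILLER),
    ]
    return "\n".join(lines)


def generate_corpus(spec: SynthSpec) -> tuple[str, list[GoldRecord]]:
    """Generate a delimiter-separated corpus and its gold records.

    Deterministic under a fixed spec (single RNG stream keyed by the seed).
    Raises ``ValueError`` for an impossible mix (a nonzero prevalence whose
    positive pattern pool is empty).
    """
    rng = random.Random(spec.seed)
    mix = dict(spec.construct_mix) if spec.construct_mix is not None else None
    hard_boost = {"easy": 0.0, "documented_limitations": 1.5, "mixed": 0.5}[
        spec.hardness
    ]

    for slot, prevalence in (("q1", spec.q1_prevalence), ("q2", spec.q2_prevalence)):
        if prevalence > 0 and not _pool(slot, True, spec.hardness, mix):
            raise ValueError(
                f"impossible construct mix: {slot} prevalence {prevalence} "
                "with no positive patterns available"
            )

    # Hard patterns that must appear at least once (verbatim regression
    # sentences) when the regime includes them.
    forced_q1 = []
    forced_q2 = []
    if spec.hardness in ("documented_limitations", "mixed") and spec.n_reports > 0:
        forced_q1 = [p for p in ("sentencewide_modifier_trap", "either_or")
                     if mix is None or mix.get(p, 1.0) > 0]
        forced_q2 = ["neg_distance_6"] if (mix is None or
                                           mix.get("neg_distance_6", 1.0) > 0) else []

    decoy_pool = _pool("decoy", False, spec.hardness, mix)
    blocks = []
    records = []
    reports_left_for_patient = 0
    age, sex = 0, "man"

    for i in range(spec.n_reports):
        if reports_left_for_patient == 0:
            reports_left_for_patient = rng.randint(1, 6)  # <= 10 per patient
            age = rng.randint(45, 82)
            sex = rng.choice(("man", "woman"))
        reports_left_for_patient -= 1

        q1 = rng.random() < spec.q1_prevalence
        q2 = rng.random() < spec.q2_prevalence

        if not q1 and forced_q1:
            q1_pattern = _INVENTORY[forced_q1.pop(0)]
        else:
            pool = _pool("q1", q1, spec.hardness, mix)
            q1_pattern = _weighted_choice(rng, pool, mix, hard_boost) if pool else None

        q2_pool = _pool("q2", q2, spec.hardness, mix)
        if q1_pattern is not None and q1_pattern.fh_only_partner:
            q2_pool = [p for p in q2_pool if p.section == "fh"]
        if not q2 and forced_q2 and (q1_pattern is None
                                     or not q1_pattern.fh_only_partner):
            q2_pattern = _INVENTORY[forced_q2.pop(0)]
        else:
            q2_pattern = (
                _weighted_choice(rng, q2_pool, mix, hard_boost) if q2_pool else None
            )

        planted = [p for p in (q1_pattern, q2_pattern) if p is not None]
        for decoy in rng.sample(decoy_pool, k=min(rng.randint(0, 2),
                                                  len(decoy_pool))):
            planted.append(decoy)

        report_id = f"r{i + 1:04d}"
        blocks.append(_render_report(rng, report_id, age, sex, planted))
        records.append(
            GoldRecord(
                report_id=report_id,
                q1=q1,
                q2=q2,
                planted_constructs=tuple(p.pattern_id for p in planted),
            )
        )

    corpus = ""
    if blocks:
        corpus = ("\n" + DELIMITER_LINE + "\n").join(blocks) + "\n" + DELIMITER_LINE + "\n"
    return corpus, records


def write_gold(records: Sequence[GoldRecord]) -> str:
    """Tab-separated gold table: report_id, q1, q2 (1/0)."""
    lines = ["report_id\tq1\tq2"]
    for record in records:
        lines.append(f"{record.report_id}\t{int(record.q1)}\t{int(record.q2)}")
    return "\n".join(lines) + "\n"


def read_gold(text: str) -> list[tuple[str, bool, bool]]:
    """Inverse of :func:`write_gold` (accepts 1/0 or true/false cells)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:3] != ["report_id", "q1", "q2"]:
        raise ValueError("gold table missing report_id/q1/q2 header")

    def parse(cell: str) -> bool:
        low = cell.strip().lower()
        if low in ("1", "true", "t", "yes"):
            return True
        if low in ("0", "false", "f", "no"):
            return False
        raise ValueError(f"unparseable boolean cell {cell!r}")

    out = []
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) < 3:
            raise ValueError(f"malformed gold row: {line!r}")
        out.append((cells[0], parse(cells[1]), parse(cells[2])))
    return out
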