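# Methods

## Task and model

`cancerhx` treats cancer-history abstraction as lexicon-driven semantic
frame construction. The unit of analysis is one H&P report; the unit of
extraction is one cancer-concept mention, recorded as a seven-slot frame
(report id, cancer term, modifiers, experiencer, negation terms, section,
sentence). Report-level answers are existential over frames: Q1 (personal
ancillary cancer) is true iff some patient-experienced, non-negated frame
resolves to a non-mesothelioma identity; Q2 (family history of any cancer)
is true iff some non-negated frame is experienced by a family member.

The central modelling assumption is that in a mesothelioma clinic
population, an unmodified generic mention ("the cancer", "tumor") refers to
the known mesothelioma unless an earlier, more specific mention says
otherwise. Reference resolution therefore scans a report's earlier frames
in reverse for the nearest *specified* frame (a named cancer, or a generic
term with modifiers) and adopts its phrase, defaulting to "mesothelioma".
A resolved phrase counts as mesothelioma iff it contains the token
`mesothelioma`, so modifier variants ("malignant mesothelioma") are still
excluded from Q1. Two deliberate consequences: negated specified frames
still serve as antecedents (specificity, not polarity, is what resolution
needs), and resolution never crosses report boundaries — reports are
classified independently even when they share a patient.

## Structural parsing

Reports are delimiter-separated blocks (default delimiter line
`=====END_OF_REPORT=====`, configurable regex), optionally named by a
`REPORT_ID: <id>` line. Sections start at lines whose leading text (before
a colon, ≤ 60 characters, case-insensitive) matches the heading inventory;
the ≤ 60-character line-start constraint prevents a mid-sentence "family
history" from opening a section (that case is handled by the experiencer
phrase rule instead). Every section is *subjective* unless its heading is
on the non-subjective list (physical exam, assessment, impression
variants): the implementable complement of a positive subjective list,
since history-style headings are open-ended. Text before any heading is a
subjective preamble. Frame builders only ever see subjective sentences.

Sentences end at `.!?` followed by whitespace and a capital/digit, or at a
hard line break. Treating every line break as a boundary deliberately
over-segments wrapped prose; the alternative — joining lines — recreates
the documented failure where unpunctuated report sections collapse into
one giant "sentence" whose distant words contaminate scope-based
attachment. Tokens are whitespace-delimited with lowercase,
edge-punctuation-stripped norms; the raw-case, punctuation-stripped form
is kept for acronym matching ("T-PLL," → norm `t-pll`, acronym form
`T-PLL`), and the determiner "all" never matches the acronym `ALL`.

## Lexicon

Eleven categories (non-cancer "-oma" words, cancer acronyms, unique
cancers, modifier descriptors, cancer-as-adjective nouns, first-degree and
other kinship, nonrelatives, family-history and non-subjective headings,
negation phrases) shipped as packaged YAML; user configs may replace or
extend per category. Validation enforces lowercase storage (except
acronyms) and disjointness of mutually exclusive categories
(kinship/nonrelatives, modifiers/negations). "Melanoma" is kept both as a
modifier descriptor and as a valid "-oma" hot-spot; users extending the
lexicon should be aware a sentence like "history of melanoma" produces a
melanoma frame, not a modifier.

A backward window "matches the modifier lexicon" iff it is *exactly
partitionable* into descriptor phrases ("small cell" + "lung") with no
leftover tokens — this is what makes window size 3 match on "small cell
lung" while sizes 5 and 4 fail on "history of small cell lung". The
partition test is dynamic programming over prefix feasibility, checked in
tests against brute-force partition enumeration; the reported phrase list
uses leftmost-longest backtracking to keep lexicon-phrase provenance.

## Dynamic-Window engine

Hot-spot cascade: (a) all "-oma"/"-omas" tokens not on the non-cancer
list; (b) only if none, all "cancer" tokens; (c) unique cancer words and
(d) exact-case acronyms unconditionally. A candidate immediately followed
by a cancer-as-adjective noun ("tumor markers") is suppressed. Candidates
are deduplicated by token position.

Window geometry (a `WindowConfig`, CLI-overridable): backward sizes
(5, 4, 3, 2, 1), tried largest-first, each evaluated only at its full
nominal size (a truncated window re-appears as the matching smaller size,
so larger-window precedence is well defined); forward look offsets
(1, 2, 3) with window size 1, modifiers only. A backward modifier match
moves the hot-spot start onto the first modifier token; forward matches do
not expand. The negation search repeats the backward-only descent from the
(expanded) span start, requiring the whole window to equal a negation
phrase. The fixed five-token ceiling is a known, preserved limitation:
"there is no family history of diabetes or cancer" yields a non-negated
family frame (a Q2 false positive) because "of diabetes or" pushes the
negation out of reach — asserted in tests as expected behaviour, not fixed
silently, since the same ceiling is what stops the engine from grabbing
unrelated distant words.

Experiencer: patient by default; a family-history section (rule A) or a
"family history (of)" phrase (rule B) sets `unknown_family`, refined to a
specific kinship term when one is present (first-degree relatives take
precedence over other relatives, leftmost match breaking ties — a fixed
order chosen for determinism). Outside rules A/B, a nonrelative mention
discards the frame entirely and a kinship mention names the relative.

## ConText-style engine

Trigger inventory compiled from the same lexicon: negation phrases become
negation triggers; "family history (of)", kinship terms and nonrelatives
become experiencer triggers (nonrelatives valued DISCARD). Only
pre-concept, forward-scoping triggers are implemented; the bare cue words
"negative"/"unremarkable" fire only when followed by "for" (a post-concept
"ROS negative." is ignored). Each trigger scopes from the token after its
phrase to the sentence end, closed early by a termination conjunction
(`but`, `however`, `although` — a ConText-family convention, chosen here as
the minimal standard set) and superseded by a later same-axis trigger.
Axes scan independently, so the experiencer trigger "family history of"
nested inside the negation trigger "no family history of" still fires —
that sentence comes out both negated and family-attributed, which is the
correct reading.

Modifier attachment is sentence-wide by default: greedy longest-phrase
descriptor matching over all tokens outside the hot-spot, the contiguous
pre-hot-spot run keeping text order, remaining matches ordered
nearest-first. The documented failure — gluing "liver" from the end of a
long surgical sentence onto "tumor" — is preserved under the default and
regression-tested; `modifier_scope="window"` switches to the windowed
search for users who want the conservative behaviour. Hot-spot
identification and the family-history *section* default are shared with
the Dynamic-Window engine, so on sentences where the negation cue sits
within window reach and no stray descriptors exist, the two engines
produce identical (term, negated, experiencer) triples — enforced as a
property test on generated easy corpora.

## Metrics

Accuracy (TP+TN)/N, precision TP/(TP+FP), recall TP/(TP+FN), F-measure
2PR/(P+R); zero denominators yield 0 with a warning. Agreement: observed
proportion, positive/negative specific agreement 2a/(2a+b+c) and
2d/(2d+b+c), and Cohen's kappa (po−pe)/(1−pe) — with two categories,
weighted kappa reduces to unweighted, so only the plain form exists. The
degenerate pe=1 case (both raters constant) is defined as kappa 1 when
po=1 else 0, with a warning. The majority-vote reference standard is the
per-report 2-of-3 consensus; note that when two of three annotators miss a
finding, the consensus inherits the miss — by design, the reference
standard is the majority, not the truth. Confidence intervals are Wilson
score intervals (via statsmodels); tabulated values use half-up rounding
to 3 decimals.

## Synthetic corpora

The generator emulates the structure of de-identified mesothelioma H&P
reports: 6 headed sections per report (chief complaint, HPI, past medical
history, family history, physical exam, assessment), an intro sentence
fixing the known mesothelioma, inert filler, and planted sentences drawn
from a fixed pattern inventory. Each pattern declares its gold (Q1, Q2)
contribution *and* the outcome each engine is expected to produce, so a
corpus doubles as a behavioural oracle: easy corpora must be recovered at
accuracy 1.0 by both engines, and on documented-limitation corpora each
engine's errors must land exactly on the patterns that predict them. The
three documented hard sentences (out-of-reach negation, sentence-wide
modifier trap, either/or construction) are planted verbatim and forced to
appear at least once in any hard corpus.

Defaults mirror the study population: Q1 prevalence 0.20, Q2 prevalence
0.27, at most a handful of reports per synthetic patient (1–6, under the
10-per-patient cap of the source data). One `random.Random` stream keyed
by the seed drives all sampling; generation is byte-reproducible.

What the generator does *not* emulate: transcription errors and
misspellings, physician stylistic variety, abbreviations outside the
lexicon, true PHI-like content, and cross-report patient continuity.
Passing the synthetic-recovery tests therefore demonstrates that the
engines implement their specified rules exactly — not that they would
reach any particular accuracy on real clinical text, where lexicon
coverage is known to dominate error rates.

## Numerical and scale choices

All coordinates are 0-based with half-open spans. The test suite runs in a
few seconds: property tests use a few hundred randomized sentences (the
oracle-equivalence acceptance test uses 1,000), and synthetic-recovery
tests use 300-report corpora at the default prevalences — large enough to
exercise every pattern with both engines while keeping the suite quick.
`scripts/acceptance.py` is fully deterministic; its `--seed` flag seeds
the (unused-by-default) randomized paths for reproducibility discipline.

## Known limitations

* Negation beyond five tokens from the expanded hot-spot is invisible to
  the windowed engine; sentence-wide scope over-reaches for the trigger
  engine. Both are faithful, documented behaviours of the respective
  methods.
* Either/or constructions ("either mesothelioma versus … adenocarcinoma")
  produce frames for both alternatives; neither engine models the
  inconclusiveness, so such sentences yield Q1 false positives.
* No syntactic parsing: negation/modifier scope is purely lexical.
* The subjective-heading inventory is a curated default, not learned from
  data; unrecognized headings leave text in the preceding section.
* Temporality (historical vs current) and certainty axes are not modelled;
  they are not needed for the two report-level questions.
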