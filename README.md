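# cancerhx

Rule-based classification of free-text **history & physical (H&P) reports**
from mesothelioma patients, answering two questions per report:

* **Q1** — does the patient have a personal history of *ancillary* cancer
  (any malignancy other than the known mesothelioma)?
* **Q2** — is there a family history of *any* cancer (mesothelioma included)?

Tissue banks and cancer registries abstract these data elements by hand from
narrative clinical notes; `cancerhx` automates the extraction for screening
and case-finding, and ships the evaluation machinery (confusion metrics,
specific agreement, Cohen's kappa) needed to measure such a system against a
human-annotated reference standard.

## How it works

Every cancer mention is captured as a seven-slot **semantic cancer frame**:
report id, cancer term, modifiers, experiencer, negation terms, section
location, and sentence text. Reports are split into sections at heading
lines, and only *subjective* sections (history narrative, as opposed to
physical exam / assessment) are searched. Two interchangeable engines fill
the frame slots:

* **Dynamic-Window** — locates cancer-concept *hot-spots* (words ending in
  "-oma" minus a non-cancer list; the word "cancer" as a fallback; unique
  cancer words such as "leukemia"; exact-case acronyms such as "SCLC"),
  then runs a variable-size bi-directional window search: backward windows
  of 5, 4, 3, 2, 1 tokens, each of which must match the modifier lexicon
  *in its entirety*, with a three-place forward look for the
  "cancer of the *location*" pattern. A backward modifier match expands the
  hot-spot (e.g. "cancer" → "small cell lung cancer") before an identical
  backward-only search for negation phrases. The experiencer defaults to
  the patient, overridden by family-history sections/phrases and kinship
  terms; mentions attributed to nonrelatives (spouse) are discarded.
* **ConText-style** — NegEx/ConText-family trigger phrases with forward
  scope: a negation or experiencer cue scopes from the trigger to the end
  of the sentence (closed by "but"/"however"/"although"), and modifiers
  attach sentence-wide. This reaches negations the five-token window
  cannot ("there is no family history of diabetes or **cancer**"), at the
  cost of occasionally fabricating concepts from distant words
  ("tumor debulking … ultrasound of the **liver**" → a "liver tumor"
  frame). Both documented behaviours are preserved and regression-tested;
  `modifier_scope="window"` opts out of sentence-wide attachment.

Frame evaluation then performs **reference resolution**: a generic mention
("the cancer") adopts the identity of the nearest preceding *specified*
frame, defaulting to mesothelioma — in this population an unanchored
generic mention most plausibly refers to the known disease. Q1 counts
patient-experienced, non-negated frames that do not resolve to
mesothelioma; Q2 counts non-negated family frames.

Because real mesothelioma H&P corpora are PHI-restricted, the package
includes a seeded synthetic-report generator (`cancerhx.synth`) that
emulates their structure — section-headed narrative, negations at
controlled distances, kinship attributions, decoys ("tumor markers",
"hematoma", "cancer conference") and the documented hard sentences — with
exact gold labels and per-engine expected behaviour for every planted
construct.

## Worked example

```bash
cancerhx synth --n 6 --seed 11 --out-corpus corpus.txt --out-gold gold.tsv
cancerhx classify corpus.txt --engine dynamic-window --dump-frames frames.tsv
```

prints

```
report_id	q1	q2	q1_evidence	q2_evidence
r0001	0	0
r0002	0	0
r0003	0	0
r0004	0	0
r0005	1	0	bladder cancer
r0006	0	1		leukemia
Reports classified: 6
Q1 positive (personal history of ancillary cancer): 1
  r0005
Q2 positive (family history of any cancer): 1
  r0006
```

Report `r0005` contains "The patient has cancer of the bladder." — the
forward look attaches "bladder" and the non-negated, patient-experienced,
non-mesothelioma frame makes the report Q1-positive. Report `r0001`
contains "The patient has no history of colon cancer.": the hot-spot
"cancer" expands over the modifier "colon", the negation search matches
"no history of", and the negated frame (visible in `frames.tsv`) correctly
leaves the report negative. Scoring predictions against gold labels:

```bash
cancerhx evaluate pred.tsv gold.tsv        # accuracy/P/R/F per question
cancerhx evaluate --annotator a1.tsv --annotator a2.tsv --annotator a3.tsv
                                           # pairwise agreement + kappa
```

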