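# Default domain lexicon for cancer-history extraction from H&P reports.
# Five top-level groups (cancer identification, modifiers, kinship, section
# headings, negation) split into eleven categories. User configs must declare
# all eleven keys; empty lists are allowed.

noncancer_oma_terms:
  - adenoma
  - hematoma
  - adenomas
  - cystadenoma
  - hamartoma
  - hematomas
  - glaucoma
  - hemangioma
  - lipoma
  - hemartoma
  - coma
  - diploma
  - aroma

cancer_acronyms:
  - ALL
  - ALCL
  - AMKL
  - ANLL
  - CTCL
  - CLL
  - AML
  - CML
  - HCC
  - HCL
  - LMM
  - TCC
  - T-PLL
  - PLL
  - SCC
  - SMLC
  - SCLC

unique_cancers:
  - hodgkin
  - leukemia
  - neoplasm
  - tumor

modifier_descriptors:
  - acute
  - acute lymphoblastic
  - acute myelogenous
  - adrenocortical
  - aids-related
  - anal
  - basal cell
  - bile duct
  - bladder
  - bone
  - brain
  - brain stem
  - breast
  - bronchial
  - central nervous system
  - cerebellar
  - cervical
  - chronic lymphocytic
  - chronic myelogenous
  - colon
  - colorectal
  - cutaneous t-cell
  - endocrine
  - endometrial
  - esophageal
  - eye
  - gallbladder
  - gastric
  - gastrointestinal
  - gastrointestinal carcinoid
  - germ cell
  - hairy cell
  - head
  - hepatocellular
  - hodgkin
  - hodgkin's
  - hypopharyngeal
  - hypothalamic
  - intraocular
  - kaposi
  - kidney
  - laryngeal
  - lip
  - liver
  - lung
  - lymphoblastic
  - lymphocytic
  - malignant
  - melanoma
  - metastatic
  - merkel cell
  - mouth
  - myelogenous
  - myeloid
  - nasal cavity
  - nasopharyngeal
  - neck
  - non-hodgkin
  - non-small cell
  - oral
  - ovarian
  - pancreas
  - pancreatic
  - paranasal
  - parathyroid
  - penile
  - pharyngeal
  - pituitary
  - plasma cell
  - pleuropulmonary
  - prostate
  - rectal
  - renal
  - renal cell
  - salivary gland
  - sinus
  - skin
  - small cell
  - small intestine
  - soft tissue
  - spinal cord
  - squamous cell
  - stomach
  - stromal
  - t-cell
  - t-cell prolymphocytic
  - testicular
  - throat
  - thymic
  - thymus
  - thymoma
  - thyroid
  - transitional cell
  - unknown
  - unknown primary site
  - uterine
  - vaginal
  - vulvar
  - wilms

cancer_as_adjective_nouns:
  - conference
  - marker
  - markers
  - registry

kinship_fdr:
  - mother
  - father
  - sister
  - sisters
  - brother
  - brothers
  - half brother
  - half sister
  - son
  - sons
  - daughter
  - daughters
  - half-brother
  - half-sister
  - step brother
  - step sister
  - step-brother
  - step-sister
  - mom
  - dad

kinship_other:
  - uncle
  - aunt
  - cousin
  - grandfather
  - grandmother
  - grandpa
  - grandma

nonrelatives:
  - husband
  - wife
  - spouse

family_history_headings:
  - family history
  - "family history:"
  - familyhistory
  - "FH:"

nonsubjective_headings:
  - Physical Exam
  - "Physical Exam:"
  - Physicalexam
  - "Physicalexam:"
  - PHYSICAL EXAMINATION
  - "PHYSICAL EXAMINATION:"
  - PHYSICALEXAMINATION
  - "PHYSICALEXAMINATION:"
  - Assessment
  - ASSESSMENT
  - "ASSESSMENT:"
  - ASSESSMENT/PLAN
  - "ASSESSMENT/PLAN:"
  - ASSESSMENT AND PLAN
  - "ASSESSMENT AND PLAN:"
  - ASSESSMENT PLAN
  - ASSESSMENT-PLAN
  - "ASSESSMENT-PLAN:"
  - IMPRESSION
  - "IMPRESSION:"

negation_phrases:
  - negative
  - negative for
  - denies
  - denies any history of
  - denies any family history of
  - negative history of
  - no family history of
  - "no"
  - unremarkable
  - unremarkable for
  - no history of
  - no history of other
  - no hx of
  - no family hx of
  - without a history of
  - without of hx of
  - without
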