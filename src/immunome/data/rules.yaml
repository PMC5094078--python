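# Immunome architecture-grammar rule file, version 1.
#
# `labels` normalises raw domain hits to grammar labels. A hit is tested
# against each label in order; the first predicate that matches wins.
# Predicates: `family` (Pfam family accession), `clan` (Pfam clan accession),
# `name` (case-insensitive match on the reported domain name; `name_prefix`
# matches a leading substring, for numbered variants like Sushi_1/Sushi_2).
#
# `families` defines the candidate and accessory rules. `required` labels
# must all be present for a call; `canonical` labels (defaults to `required`)
# must all be present for the call to be eligible for "complete" status;
# `optional` labels are recorded as evidence/subtype when present.

version: 1

tir_equivalence: [TIR, TIR_2]

# Domains that, alongside a TIR/TIR_2, route a transcript to the novelty
# detector instead of the conserved-candidate grammar (distinguishes e.g.
# NG3 = TIR + DD + kinase from MyD88 = TIR + DD).
novelty_indicative: [Pkinase, Pkinase_Tyr, Ras, Roc, COR, Miro, SH3, SAM, BTK, CBM]

labels:
  - {label: TIR,        family: PF01582, name: TIR}
  - {label: TIR_2,      family: PF13676, name: TIR_2}
  - {label: DUF1863,    name: DUF1863}
  - {label: LRR,        clan: CL0022}
  - {label: Ig,         clan: CL0011}
  - {label: RHD,        family: PF00554, name: RHD}
  - {label: Ank,        family: PF00023, name_prefix: Ank}
  - {label: NACHT,      family: PF05729, name: NACHT}
  - {label: CARD,       family: PF00619, name: CARD}
  - {label: PYD,        family: PF02758, name: PYRIN}
  - {label: DED,        family: PF01335, name: DED}
  # DD falls back to clan CL0041 (death-fold) for hits not annotated to a
  # specific member family; tested after CARD/PYD/DED so those stay distinct.
  - {label: DD,         family: PF00531, clan: CL0041, name: Death}
  - {label: Collagen,   family: PF01391, name: Collagen}
  - {label: Fibrinogen, family: PF00147, name_prefix: Fibrinogen}
  - {label: SRCR,       family: PF00530, name: SRCR}
  - {label: Lectin_C,   family: PF00059, name: Lectin_C}
  - {label: WAP,        family: PF00095, name: WAP}
  - {label: Pkinase_Tyr, family: PF07714, name: Pkinase_Tyr}
  - {label: Pkinase,    family: PF00069, name: Pkinase}
  - {label: Ras,        family: PF00071, name: Ras}
  - {label: Miro,       family: PF08477, name: Miro}
  - {label: Roc,        name: Roc}
  - {label: COR,        name: COR}
  - {label: BTK,        family: PF00779, name: BTK}
  - {label: SH3,        family: PF00018, name_prefix: SH3}
  - {label: SAM,        family: PF00536, name_prefix: SAM}
  - {label: CBM,        name_prefix: CBM}
  - {label: CUB,        family: PF00431, name_prefix: CUB}
  - {label: EGF_CA,     family: PF07645, name_prefix: EGF}
  - {label: Sushi,      family: PF00084, name_prefix: Sushi}
  - {label: Trypsin,    family: PF00089, name: Trypsin}

# Candidate families, in classification precedence order (most specific
# co-domain first). `repeat_classes` are tallied into n_repeat_domains.
families:
  NLR:
    required: [NACHT]
    canonical: [NACHT, LRR]
    optional: [CARD, PYD, DD, DED]
    repeat_classes: [LRR]
  TLR:
    required: [TIR|TIR_2, LRR]
    repeat_classes: [LRR]
  IL1R_like:
    required: [TIR|TIR_2, Ig]
    repeat_classes: [Ig]
  MyD88:
    required: [TIR|TIR_2, DD]
  NFKB:
    required: [RHD]
    canonical: [RHD, Ank]
    repeat_classes: [Ank]

accessory:
  CniFL:
    required: [Collagen, Ig, Fibrinogen]
    optional: [WAP]
    repeat_classes: [Ig]
  MASP:
    # six domain slots; min_slots relaxes the all-six default
    slots: {CUB: 2, EGF_CA: 1, Sushi: 2, Trypsin: 1}
    min_slots: 6
    requires_reference_homology: true
  SRCR:
    required: [SRCR]
  CTLD:
    required: [Lectin_C]

# Complement components are called by homology subject-name patterns only
# (case-insensitive regular expressions).
complement_patterns:
  C3:      'complement[ _]?c3(?=[ _|]|$)|co3_'
  FactorB: 'factor[ _]?b(?=[ _|]|$)|cfab'
  C6:      'complement[ _]?c6(?=[ _|]|$)|co6_'
  FactorI: 'factor[ _]?i(?=[ _|]|$)|cfai'
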