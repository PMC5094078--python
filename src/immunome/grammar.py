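"""Candidate-gene identification grammar.

Conserved innate-immune receptor/adaptor families are called from domain
architecture alone:

* TLR       — TIR (PF01582, or the bacterial-type TIR_2, PF13676) + >=1 LRR (CL0022)
* MyD88     — TIR (or TIR_2) + a death domain
* IL-1R-like— TIR (or TIR_2) + >=1 immunoglobulin domain (CL0011)
* NF-κB     — Rel homology domain (PF00554) + >=1 ankyrin repeat (PF00023);
              an RHD without ankyrin repeats is kept only as a partial call
* NLR       — NACHT + >=1 LRR, optionally an N-terminal death-fold domain
              (CARD PF00619 / PYD PF02758 / DD PF00531 / DED PF01335)

A call is *complete* only when the ORF has both start and stop codons, the
peptide received at least one peptide-level homology hit, and all canonical
domains of its family are present.  Transcripts whose TIR co-occurs with
novelty-indicative domains (kinases, GTPase modules, SH3/SAM/BTK/CBM) are
deliberately NOT called here; they belong to the novelty detector.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional

from .records import (
    DEATH_FOLDS,
    DomainHit,
    DomainSubsequence,
    FamilyCall,
    TmdSegment,
    TranscriptAnnotation,
)
from .rules import RuleSet, load_rules

log = logging.getLogger(__name__)

# Fraction of the peptide length within which all TMD midpoints must fall to
# count as N-terminally clustered (the membrane-NLR subtype signal).
DEFAULT_NTERM_FRACTION = 0.30


def _labelled(ann: TranscriptAnnotation, rules: RuleSet):
    """(hit, label) pairs for hits that normalise to a grammar label."""
    return [(h, lab) for h, lab in rules.label_hits(ann.domains) if lab is not None]


def has_novelty_route(ann: TranscriptAnnotation, rules: RuleSet) -> bool:
    """True when the transcript should be routed to the novelty detector.

    A TIR/TIR_2-bearing transcript carrying any novelty-indicative co-domain
    (kinase, Ras/Roc/COR/Miro, SH3, SAM, BTK, CBM) is never a conserved
    candidate: this is what separates NG3 (TIR + DD + kinase) from MyD88
    (TIR + DD).
    """
    labels = {lab for _, lab in _labelled(ann, rules)}
    return bool(labels & rules.tir_labels) and bool(labels & rules.novelty_indicative)


def classify_candidate(
    ann: TranscriptAnnotation, rules: RuleSet | None = None
) -> Optional[FamilyCall]:
    """Return at most one conserved-candidate FamilyCall, or None.

    Family precedence is the rule-file order (NLR > TLR > IL-1R-like >
    MyD88 > NF-κB: most specific co-domain first); the first matching rule
    wins and ties are logged.
    """
    rules = rules or load_rules()
    pairs = _labelled(ann, rules)
    labels = {lab for _, lab in pairs}
    if not labels:
        return None
    if has_novelty_route(ann, rules):
        return None

    matching = [r for r in rules.families if r.matches(labels)]
    if not matching:
        return None
    if len(matching) > 1:
        log.info(
            "%s matches %s; keeping %s by precedence",
            ann.transcript_id, [r.family for r in matching], matching[0].family,
        )
    rule = matching[0]

    relevant = set()
    for entry in (*rule.required, *rule.canonical, *rule.optional, *rule.repeat_classes):
        relevant.update(entry.split("|"))
    evidence = [h for h, lab in pairs if lab in relevant]
    repeat_counts = Counter(lab for _, lab in pairs)
    n_repeats = {cls: repeat_counts.get(cls, 0) for cls in rule.repeat_classes}

    death_fold = "none"
    if rule.family == "NLR":
        for df in DEATH_FOLDS:  # first by fixed superfamily order
            if df in labels:
                death_fold = df
                break

    call = FamilyCall(
        transcript_id=ann.transcript_id,
        family=rule.family,
        completeness="partial",
        evidence=sorted(evidence, key=lambda h: (h.aa_start, h.aa_end)),
        n_repeat_domains=n_repeats,
        death_fold_type=death_fold,
    )
    if rule.family == "NFKB" and "Ank" not in labels:
        call.notes.append("RHD-only")
    call.completeness = assess_completeness(ann, call, rules)
    return detect_tmd_subtype(call, ann.tmds, ann.orf.peptide_length)


def assess_completeness(
    ann: TranscriptAnnotation, call: FamilyCall, rules: RuleSet | None = None
) -> str:
    """Grade a call: complete needs a full ORF (start + stop), at least one
    peptide-level homology hit, and all canonical family domains."""
    rules = rules or load_rules()
    labels = {lab for _, lab in _labelled(ann, rules)}
    rule = next((r for r in rules.families if r.family == call.family), None)
    if rule is None:  # accessory family: no canonical set beyond required
        canonical_ok = True
    else:
        canonical_ok = rule.canonical_satisfied(labels)
    ok = (
        ann.orf.has_start_codon
        and ann.orf.has_stop_codon
        and len(ann.peptide_homology) >= 1
        and canonical_ok
    )
    return "complete" if ok else "partial"


def detect_tmd_subtype(
    call: FamilyCall,
    tmds: Iterable[TmdSegment],
    peptide_length: int,
    n_terminal_fraction: float = DEFAULT_NTERM_FRACTION,
) -> FamilyCall:
    """Annotate membrane topology on a call.

    ``membrane_bound`` is set when >=1 helix is present;
    ``tmd_n_terminal_clustered`` when *all* helix midpoints lie within the
    first ``n_terminal_fraction`` of the peptide — the membrane-bound NLR
    subtype carries 3–5 helices clustered at the N-terminus.
    """
    if peptide_length <= 0:
        raise ValueError("peptide_length must be positive")
    if not (0 < n_terminal_fraction <= 1):
        raise ValueError("n_terminal_fraction must be in (0, 1]")
    tmds = list(tmds)
    call.n_tmd = len(tmds)
    call.membrane_bound = call.n_tmd >= 1
    call.tmd_n_terminal_clustered = bool(tmds) and all(
        t.midpoint <= n_terminal_fraction * peptide_length for t in tmds
    )
    return call


def classify_other_immune(
    ann: TranscriptAnnotation,
    masp_reference_ids: frozenset[str] | set[str] = frozenset(),
    rules: RuleSet | None = None,
) -> list[FamilyCall]:
    """Call accessory immune families (CniFL, MASP, SRCR, C-type lectin).

    CniFL requires Collagen (PF01391) + >=1 Ig (CL0011) + Fibrinogen
    (PF00147) and records Ig count, WAP presence and membrane topology.
    MASP requires the six-slot domain complement (CUB x2, EGF-like
    calcium-binding, Sushi x2, Peptidase S1) *and* homology to a supplied
    reference MASP.  SRCR and CTLD are single-domain calls.
    """
    rules = rules or load_rules()
    pairs = _labelled(ann, rules)
    labels = {lab for _, lab in pairs}
    counts = Counter(lab for _, lab in pairs)
    calls: list[FamilyCall] = []

    for family, spec in rules.accessory.items():
        if "slots" in spec:  # MASP-style multi-slot rule
            slots: dict[str, int] = spec["slots"]
            n_satisfied = sum(
                min(counts.get(lab, 0), need) for lab, need in slots.items()
            )
            min_slots = int(spec.get("min_slots", sum(slots.values())))
            if n_satisfied < min_slots:
                continue
            if spec.get("requires_reference_homology"):
                if not any(
                    h.subject_id in masp_reference_ids for h in ann.homology
                ):
                    continue
        else:
            required = tuple(spec["required"])
            if not all(
                any(alt in labels for alt in entry.split("|")) for entry in required
            ):
                continue
        evidence = [h for h, lab in pairs if lab is not None]
        call = FamilyCall(
            transcript_id=ann.transcript_id,
            family=family,
            completeness="partial",
            evidence=sorted(evidence, key=lambda h: (h.aa_start, h.aa_end)),
        )
        if family == "CniFL":
            call.n_repeat_domains = {"Ig": counts.get("Ig", 0)}
            call.has_wap = "WAP" in labels
        call.completeness = assess_completeness(ann, call, rules)
        detect_tmd_subtype(call, ann.tmds, ann.orf.peptide_length)
        calls.append(call)
    return calls


def presence_flags(
    catalog: Iterable[TranscriptAnnotation], rules: RuleSet | None = None
) -> dict[str, bool]:
    """Presence/absence of complement components (C3, Factor B, C6, Factor I).

    These have no domain rule; a family is present when any homology hit's
    subject id matches its configured name pattern.
    """
    rules = rules or load_rules()
    flags = {fam: False for fam in rules.complement_patterns}
    for ann in catalog:
        for h in ann.homology:
            for fam, pat in rules.complement_patterns.items():
                if pat.search(h.subject_id):
                    flags[fam] = True
    return flags


def validate_topology(calls: Iterable[FamilyCall]) -> list[str]:
    """Warn where topology defies the conserved expectations.

    TLR and IL-1R-like peptides are expected to carry transmembrane helices;
    MyD88 and NF-κB are cytosolic.  Warnings never change calls.
    """
    warns = []
    for call in calls:
        if call.family in ("TLR", "IL1R_like") and call.n_tmd == 0:
            warns.append(f"{call.transcript_id}: {call.family} without a TMD")
        elif call.family in ("MyD88", "NFKB") and call.n_tmd > 0:
            warns.append(
                f"{call.transcript_id}: {call.family} with {call.n_tmd} TMD(s)"
            )
    return warns


def extract_domain_subsequence(
    ann: TranscriptAnnotation, accession: str
) -> list[DomainSubsequence]:
    """Clip the peptide to each envelope of ``accession`` (e.g. the NACHT
    domain ahead of phylogenetic alignment), in coordinate order."""
    pep = ann.orf.peptide
    out = []
    for hit in sorted(ann.domains, key=lambda h: (h.aa_start, h.aa_end)):
        if accession not in (hit.family_accession, hit.domain_name):
            continue
        if hit.aa_end > len(pep):
            raise ValueError(
                f"{ann.transcript_id}: envelope {hit.aa_start}..{hit.aa_end} "
                f"exceeds peptide length {len(pep)}"
            )
        out.append(
            DomainSubsequence(
                transcript_id=ann.transcript_id,
                accession=accession,
                aa_start=hit.aa_start,
                aa_end=hit.aa_end,
                sequence=pep[hit.aa_start - 1: hit.aa_end],
            )
        )
    return out


def write_subsequences_fasta(subs: Iterable[DomainSubsequence], path) -> None:
    with open(path, "w") as fh:
        for s in subs:
            fh.write(f">{s.transcript_id}/{s.aa_start}-{s.aa_end} {s.accession}\n")
            fh.write(s.sequence + "\n")
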