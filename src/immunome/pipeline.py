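"""End-to-end classification of a merged annotation catalog.

Routing is exclusive: a transcript receives either a conserved/accessory
FamilyCall or a NoveltyCall, never both.  TIR-bearing transcripts with
novelty-indicative co-domains go to the novelty detector even when they
would superficially satisfy a conserved rule; TIR-bearing transcripts that
match no rule and carry no (or only *N. vectensis*) annotation are screened
for novel architectures as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grammar import (
    classify_candidate,
    classify_other_immune,
    has_novelty_route,
    presence_flags,
    validate_topology,
)
from .novelty import (
    KnownArchitectureCatalog,
    annotation_status,
    call_novelty,
    tir_like_labels,
)
from .records import FamilyCall, NoveltyCall, TranscriptAnnotation
from .rules import RuleSet, load_rules


@dataclass
class ClassificationResult:
    family_calls: list[FamilyCall] = field(default_factory=list)
    novelty_calls: list[NoveltyCall] = field(default_factory=list)
    complement_presence: dict[str, bool] = field(default_factory=dict)
    topology_warnings: list[str] = field(default_factory=list)

    def calls_for(self, transcript_id: str) -> list:
        return [
            c
            for c in (*self.family_calls, *self.novelty_calls)
            if c.transcript_id == transcript_id
        ]


def classify_catalog(
    catalog: list[TranscriptAnnotation],
    rules: RuleSet | None = None,
    known: KnownArchitectureCatalog | None = None,
    masp_reference_ids: frozenset[str] | set[str] = frozenset(),
) -> ClassificationResult:
    """Classify every transcript; deterministic under input permutation.

    Calls are emitted in transcript-id order so that shuffling the catalog
    cannot change the result.
    """
    rules = rules or load_rules()
    result = ClassificationResult()
    for ann in sorted(catalog, key=lambda a: a.transcript_id):
        tir_bearing = bool(
            {lab for _, lab in rules.label_hits(ann.domains) if lab}
            & tir_like_labels(rules)
        )
        if tir_bearing and has_novelty_route(ann, rules):
            result.novelty_calls.append(call_novelty(ann, known, rules))
            continue
        call = classify_candidate(ann, rules)
        if call is not None:
            result.family_calls.append(call)
            continue
        accessory = classify_other_immune(ann, masp_reference_ids, rules)
        if accessory:
            result.family_calls.extend(accessory)
            continue
        if tir_bearing and annotation_status(ann) in ("no_hits", "nvectensis_only"):
            result.novelty_calls.append(call_novelty(ann, known, rules))
    result.complement_presence = presence_flags(catalog, rules)
    result.topology_warnings = validate_topology(result.family_calls)
    return result
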