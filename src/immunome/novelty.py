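"""Detection of novel TIR/TIR_2-domain architectures.

Transcripts bearing a TIR (PF01582) or bacterial-type TIR_2 (PF13676) domain
but lacking informative homology annotation — no database hits at all, or
hits only against *Nematostella vectensis* predicted proteins — are screened
for novel domain architectures and matched against three recurrent named
patterns plus a TIR-only class:

* NG1 — LRR + a GTPase module (Miro/Ras/Roc) + TIR_2, with an optional
  low-threshold COR domain downstream (recorded, not required);
* NG2 — one or two TIR_2 domains upstream of a BTK zinc-finger motif;
* NG3 — an overlapping kinase pair (Pkinase/Pkinase_Tyr) + death domain +
  TIR or TIR_2, with optional SH3/Roc/COR (recorded);
* TIR-only — nothing but TIR/TIR_2, or the TIR-like DUF1863.

Anything else TIR-bearing is ``unmatched_novel``.  Signatures are also
screened against a local catalog of already-described architectures.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable

from .records import (
    ArchitectureSignature,
    NoveltyCall,
    TranscriptAnnotation,
)
from .rules import RuleSet, load_rules, _data_path

log = logging.getLogger(__name__)

NVECTENSIS = "Nematostella vectensis"

# Envelope overlap (fraction of the shorter hit) above which same-clan hits
# collapse to the better-scoring one; motivated by kinase-model pairs that
# always overlap on the same segment.
OVERLAP_COLLAPSE_FRACTION = 0.5


class KnownArchitectureCatalog:
    """A local set of already-described TIR architectures.

    Replaces a live domain-architecture database lookup; order-sensitive by
    default because published architectures are reported N- to C-terminal.
    """

    def __init__(
        self,
        signatures: Iterable[tuple[tuple[str, ...], str]],
        order_sensitive: bool = True,
    ):
        self.order_sensitive = order_sensitive
        self.provenance: dict[tuple[str, ...], str] = {}
        for sig, prov in signatures:
            key = sig if order_sensitive else tuple(sorted(sig))
            if key in self.provenance:
                raise ValueError(f"duplicate catalog signature {sig}")
            self.provenance[key] = prov

    def __len__(self) -> int:
        return len(self.provenance)

    def __contains__(self, labels: tuple[str, ...]) -> bool:
        key = labels if self.order_sensitive else tuple(sorted(labels))
        return key in self.provenance

    @classmethod
    def from_tsv(cls, path: str | Path | None = None, order_sensitive: bool = True):
        path = Path(path) if path else _data_path("known_architectures.tsv")
        sigs = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("signature\t"):
                    continue
                sig, prov = line.split("\t")
                sigs.append((tuple(sig.split("-")), prov))
        return cls(sigs, order_sensitive=order_sensitive)


def build_signature(
    ann: TranscriptAnnotation,
    rules: RuleSet | None = None,
    overlap_fraction: float = OVERLAP_COLLAPSE_FRACTION,
) -> ArchitectureSignature:
    """Order labelled hits N- to C-terminal and collapse redundant overlaps.

    Hits whose envelopes overlap by more than ``overlap_fraction`` of the
    shorter hit *and* share a Pfam clan are merged, keeping the lower
    E-value (e.g. Pkinase/Pkinase_Tyr doublets).  Unlabelled hits are
    dropped from the signature.
    """
    rules = rules or load_rules()
    pairs = [
        (rules.with_clan(h), lab)
        for h, lab in rules.label_hits(ann.domains)
        if lab is not None
    ]
    pairs.sort(key=lambda p: (p[0].aa_start, p[0].aa_end, p[0].e_value))

    kept: list[tuple] = []  # (hit, label)
    for hit, lab in pairs:
        merged = False
        for i, (prev, plab) in enumerate(kept):
            overlap = min(hit.aa_end, prev.aa_end) - max(hit.aa_start, prev.aa_start) + 1
            shorter = min(hit.length, prev.length)
            same_clan = (
                hit.clan_accession
                and hit.clan_accession == prev.clan_accession
            )
            if overlap > overlap_fraction * shorter and same_clan:
                if hit.e_value < prev.e_value:
                    kept[i] = (hit, lab)
                merged = True
                break
        if not merged:
            kept.append((hit, lab))
    kept.sort(key=lambda p: (p[0].aa_start, p[0].aa_end))
    return ArchitectureSignature(
        transcript_id=ann.transcript_id, labels=tuple(lab for _, lab in kept)
    )


def annotation_status(ann: TranscriptAnnotation) -> str:
    """no_hits / nvectensis_only / annotated, from homology subject species."""
    if not ann.homology:
        return "no_hits"
    if all(h.subject_species == NVECTENSIS for h in ann.homology):
        return "nvectensis_only"
    return "annotated"


def tir_like_labels(rules: RuleSet) -> frozenset[str]:
    """TIR, TIR_2 and the TIR-like DUF1863 (seen in place of TIR in
    TIR-only architectures)."""
    return rules.tir_labels | {"DUF1863"}


def candidate_novel_set(
    catalog: Iterable[TranscriptAnnotation], rules: RuleSet | None = None
) -> list[TranscriptAnnotation]:
    """TIR/TIR_2-bearing transcripts with no or *N. vectensis*-only hits."""
    rules = rules or load_rules()
    out = []
    for ann in catalog:
        labels = {lab for _, lab in rules.label_hits(ann.domains) if lab}
        if not labels & tir_like_labels(rules):
            continue
        if annotation_status(ann) in ("no_hits", "nvectensis_only"):
            out.append(ann)
    return out


def match_named_pattern(
    signature: ArchitectureSignature, rules: RuleSet | None = None
) -> tuple[str, list[str]]:
    """Match a signature to NG1/NG2/NG3/TIR_only; returns (label, notes).

    The predicate is a pure function of the ordered label tuple.
    """
    rules = rules or load_rules()
    labels = signature.labels
    label_set = set(labels)
    notes: list[str] = []

    # NG1: LRR + >=1 GTPase-module domain + TIR_2 (COR optional, recorded)
    if (
        "LRR" in label_set
        and label_set & {"Miro", "Ras", "Roc"}
        and "TIR_2" in label_set
    ):
        if "COR" in label_set:
            notes.append("COR downstream of GTPase module")
        return "NG1", notes

    # NG2: one or two TIR_2 domains upstream of a BTK motif
    if "BTK" in label_set:
        tir2_pos = [i for i, lab in enumerate(labels) if lab == "TIR_2"]
        btk_first = labels.index("BTK")
        if 1 <= len(tir2_pos) <= 2 and all(i < btk_first for i in tir2_pos):
            return "NG2", notes

    # NG3: kinase + death domain + TIR/TIR_2 (SH3/Roc/COR optional)
    if (
        label_set & {"Pkinase", "Pkinase_Tyr"}
        and "DD" in label_set
        and label_set & {"TIR", "TIR_2"}
    ):
        extras = label_set & {"SH3", "Roc", "COR"}
        if extras:
            notes.append("additional domains: " + ", ".join(sorted(extras)))
        return "NG3", notes

    # TIR-only: nothing beyond TIR/TIR_2/DUF1863
    if label_set and label_set <= tir_like_labels(rules):
        return "TIR_only", notes

    return "unmatched_novel", notes


def screen_against_catalog(
    signature: ArchitectureSignature, catalog: KnownArchitectureCatalog
) -> str:
    """'known' when the exact signature is catalogued, else 'novel'."""
    if len(catalog) == 0:
        warnings.warn("empty known-architecture catalog: everything is novel")
        return "novel"
    return "known" if signature.labels in catalog else "novel"


def call_novelty(
    ann: TranscriptAnnotation,
    known: KnownArchitectureCatalog | None = None,
    rules: RuleSet | None = None,
) -> NoveltyCall:
    """Build the full NoveltyCall for one transcript."""
    rules = rules or load_rules()
    sig = build_signature(ann, rules)
    pattern, notes = match_named_pattern(sig, rules)
    call = NoveltyCall(
        transcript_id=ann.transcript_id,
        pattern=pattern,
        annotation_status=annotation_status(ann),
        signature=sig,
        notes=notes,
    )
    if known is not None:
        call.catalog_status = screen_against_catalog(sig, known)
    return call
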