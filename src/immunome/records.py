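"""Core record types shared across the pipeline.

Coordinates are 1-based inclusive amino-acid envelope coordinates throughout
(the Pfam/HMMER convention); every writer and reader in :mod:`immunome.ingest`
documents this.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

_PF_RE = re.compile(r"^PF\d{5}$")
_CL_RE = re.compile(r"^CL\d{4}$")


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-style domain hit on a transcript's predicted peptide."""

    transcript_id: str
    domain_name: str
    family_accession: str  # e.g. "PF01582"; "" when unknown
    clan_accession: str    # e.g. "CL0022"; "" when the family has no clan
    aa_start: int          # 1-based inclusive
    aa_end: int            # 1-based inclusive
    e_value: float

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(
                f"bad envelope {self.aa_start}..{self.aa_end} on {self.transcript_id}"
            )
        if self.family_accession and not _PF_RE.match(self.family_accession):
            raise ValueError(f"bad Pfam family accession {self.family_accession!r}")
        if self.clan_accession and not _CL_RE.match(self.clan_accession):
            raise ValueError(f"bad Pfam clan accession {self.clan_accession!r}")
        if self.e_value < 0:
            raise ValueError("negative E-value")

    @property
    def length(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclass
class OrfRecord:
    """A predicted open reading frame with completeness flags.

    ``has_start_codon``/``has_stop_codon`` come from an annotation flag
    ("complete", "5prime_partial", "3prime_partial", "internal") or are
    inferred from the peptide itself (leading M, trailing ``*``).
    """

    transcript_id: str
    orf_id: str
    peptide: str
    has_start_codon: bool
    has_stop_codon: bool
    coding_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.coding_sequence is not None:
            n = len(self.coding_sequence)
            if n not in (3 * self.peptide_length, 3 * self.peptide_length + 3):
                raise ValueError(
                    f"CDS length {n} inconsistent with peptide length "
                    f"{self.peptide_length} for {self.orf_id}"
                )

    @property
    def peptide_length(self) -> int:
        return len(self.peptide)

    @property
    def is_complete(self) -> bool:
        return self.has_start_codon and self.has_stop_codon


@dataclass(frozen=True)
class TmdSegment:
    """A predicted transmembrane helix (1-based inclusive residue range)."""

    transcript_id: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise ValueError("TMD segment start > end")

    @property
    def midpoint(self) -> float:
        return (self.aa_start + self.aa_end) / 2.0


@dataclass(frozen=True)
class HomologyHit:
    """A retained BLAST-style hit against a labelled database."""

    transcript_id: str
    database_label: str       # "swissprot" | "trembl" | "custom"
    subject_id: str
    subject_species: str
    e_value: float
    query_level: str = "peptide"  # "peptide" (BLASTp) or "nucleotide" (BLASTx)

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("negative E-value")
        if self.query_level not in ("peptide", "nucleotide"):
            raise ValueError(f"bad query_level {self.query_level!r}")


@dataclass
class TranscriptAnnotation:
    """All merged evidence for one transcript — the unit the grammar consumes."""

    transcript_id: str
    gene_group_id: str
    species_label: str
    orf: OrfRecord
    domains: list[DomainHit] = field(default_factory=list)
    tmds: list[TmdSegment] = field(default_factory=list)
    homology: list[HomologyHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_group_id:
            raise ValueError("empty gene_group_id")
        for child in (*self.domains, *self.tmds, *self.homology, self.orf):
            if child.transcript_id != self.transcript_id:
                raise ValueError(
                    f"child record {child!r} does not belong to {self.transcript_id}"
                )

    @property
    def peptide_homology(self) -> list[HomologyHit]:
        return [h for h in self.homology if h.query_level == "peptide"]


# --- call records -----------------------------------------------------------

CANDIDATE_FAMILIES = ("TLR", "MyD88", "IL1R_like", "NFKB", "NLR")
ACCESSORY_FAMILIES = ("CniFL", "MASP", "SRCR", "CTLD")
COMPLEMENT_FAMILIES = ("C3", "FactorB", "C6", "FactorI")
DEATH_FOLDS = ("CARD", "PYD", "DD", "DED")
NOVEL_PATTERNS = ("NG1", "NG2", "NG3", "TIR_only", "unmatched_novel")


@dataclass
class FamilyCall:
    """A family assignment with completeness, subtype flags and evidence."""

    transcript_id: str
    family: str
    completeness: str                    # "complete" | "partial"
    evidence: list[DomainHit] = field(default_factory=list)
    n_repeat_domains: dict[str, int] = field(default_factory=dict)  # LRR/Ank/Ig
    death_fold_type: str = "none"        # CARD | PYD | DD | DED | none
    membrane_bound: bool = False
    n_tmd: int = 0
    tmd_n_terminal_clustered: bool = False
    has_wap: bool = False                # CniFL only
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.completeness not in ("complete", "partial"):
            raise ValueError(f"bad completeness {self.completeness!r}")
        if self.death_fold_type != "none" and self.family != "NLR":
            raise ValueError("death-fold subtype recorded on a non-NLR call")
        if self.membrane_bound and self.n_tmd < 1:
            raise ValueError("membrane_bound call with zero TMDs")


@dataclass(frozen=True)
class ArchitectureSignature:
    """Ordered domain-label tuple after overlap collapsing (N- to C-terminal)."""

    transcript_id: str
    labels: tuple[str, ...]

    def __str__(self) -> str:  # e.g. "LRR-Ras-COR-TIR_2"
        return "-".join(self.labels)


@dataclass
class NoveltyCall:
    """A TIR/TIR_2-bearing architecture matched to a named novel pattern."""

    transcript_id: str
    pattern: str              # NG1 | NG2 | NG3 | TIR_only | unmatched_novel
    annotation_status: str    # no_hits | nvectensis_only | annotated
    signature: ArchitectureSignature
    catalog_status: str = "novel"   # "known" | "novel" vs the reference catalog
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pattern not in NOVEL_PATTERNS:
            raise ValueError(f"bad novelty pattern {self.pattern!r}")
        if self.annotation_status not in ("no_hits", "nvectensis_only", "annotated"):
            raise ValueError(f"bad annotation_status {self.annotation_status!r}")


@dataclass(frozen=True)
class DomainSubsequence:
    """A peptide substring clipped to one domain envelope (e.g. NACHT)."""

    transcript_id: str
    accession: str
    aa_start: int
    aa_end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.aa_end - self.aa_start + 1:
            raise ValueError("subsequence length disagrees with envelope")


def default_gene_group(transcript_id: str, pattern: str = r"_i\d+$") -> str:
    """Strip an assembler isoform suffix (Trinity-style ``_i<n>``).

    Falls back to the transcript id itself when the pattern does not match,
    so ungrouped catalogs count each contig once.
    """
    stripped = re.sub(pattern, "", transcript_id)
    return stripped or transcript_id
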