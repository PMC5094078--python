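"""Loading and evaluation of the data-driven architecture-grammar rules.

The grammar is configured by a versioned YAML file (shipped under
``immunome/data/rules.yaml``) that defines

* ``labels`` — how raw domain hits (Pfam family/clan accessions, domain
  names) normalise to grammar labels such as ``TIR``, ``LRR`` or ``NACHT``;
* ``families`` — the conserved candidate-receptor rules, in precedence order;
* ``accessory`` — lectin/complement-receptor rules (CniFL, MASP, SRCR, CTLD);
* ``complement_patterns`` — homology-name regexes for presence/absence calls.

Rules that cite a Pfam clan (e.g. LRR = CL0022, Ig = CL0011) match on the
clan accession; rules that cite a family (e.g. TIR = PF01582) match on the
family accession, with the domain name as a fallback for hits lacking one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .records import DomainHit

__all__ = ["LabelRule", "FamilyRule", "RuleSet", "load_rules", "load_clan_map"]


@dataclass(frozen=True)
class LabelRule:
    label: str
    family: str = ""
    clan: str = ""
    name: str = ""
    name_prefix: str = ""

    def matches(self, hit: DomainHit) -> bool:
        if self.family and hit.family_accession == self.family:
            return True
        if self.clan and hit.clan_accession == self.clan:
            return True
        name = hit.domain_name.lower()
        if self.name and name == self.name.lower():
            return True
        if self.name_prefix and name.startswith(self.name_prefix.lower()):
            return True
        return False


@dataclass(frozen=True)
class FamilyRule:
    """A candidate/accessory family rule over normalised labels.

    ``required`` entries may be alternations ("TIR|TIR_2"); every entry must
    be satisfied by at least one label for the rule to match.  ``canonical``
    (defaulting to ``required``) is the set additionally demanded before a
    call may be graded *complete*.
    """

    family: str
    required: tuple[str, ...]
    canonical: tuple[str, ...]
    optional: tuple[str, ...] = ()
    repeat_classes: tuple[str, ...] = ()

    @staticmethod
    def _satisfied(entry: str, labels: set[str]) -> bool:
        return any(alt in labels for alt in entry.split("|"))

    def matches(self, labels: set[str]) -> bool:
        if not self.required:
            raise ValueError(f"rule {self.family} has no required domains")
        return all(self._satisfied(e, labels) for e in self.required)

    def canonical_satisfied(self, labels: set[str]) -> bool:
        return all(self._satisfied(e, labels) for e in self.canonical)


@dataclass
class RuleSet:
    version: int
    labels: list[LabelRule]
    families: list[FamilyRule]           # precedence order
    accessory: dict[str, dict]
    complement_patterns: dict[str, re.Pattern]
    tir_labels: frozenset[str]
    novelty_indicative: frozenset[str]
    clan_map: dict[str, str] = field(default_factory=dict)

    def label_of(self, hit: DomainHit) -> Optional[str]:
        """Normalise one hit to a grammar label (first matching predicate)."""
        hit = self.with_clan(hit)
        for rule in self.labels:
            if rule.matches(hit):
                return rule.label
        return None

    def with_clan(self, hit: DomainHit) -> DomainHit:
        """Fill a missing clan accession from the shipped family→clan map."""
        if hit.clan_accession or not hit.family_accession:
            return hit
        clan = self.clan_map.get(hit.family_accession, "")
        if not clan:
            return hit
        return DomainHit(
            hit.transcript_id, hit.domain_name, hit.family_accession,
            clan, hit.aa_start, hit.aa_end, hit.e_value,
        )

    def label_hits(
        self, hits: Iterable[DomainHit]
    ) -> list[tuple[DomainHit, Optional[str]]]:
        return [(h, self.label_of(h)) for h in hits]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("immunome").joinpath("data", name)))


def load_clan_map(path: str | Path | None = None) -> dict[str, str]:
    """Read the two-column family→clan TSV asset."""
    path = Path(path) if path else _data_path("clan_map.tsv")
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("family_accession"):
                continue
            fam, clan = line.split("\t")
            mapping[fam] = clan
    return mapping


def load_rules(
    path: str | Path | None = None, clan_map_path: str | Path | None = None
) -> RuleSet:
    """Load the grammar rule file (the shipped default when ``path`` is None)."""
    path = Path(path) if path else _data_path("rules.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    labels = [LabelRule(label=d.pop("label"), **d) for d in raw["labels"]]
    families = []
    for fam, spec in raw["families"].items():
        required = tuple(spec["required"])
        families.append(
            FamilyRule(
                family=fam,
                required=required,
                canonical=tuple(spec.get("canonical", required)),
                optional=tuple(spec.get("optional", ())),
                repeat_classes=tuple(spec.get("repeat_classes", ())),
            )
        )
    complement = {
        fam: re.compile(pat, re.IGNORECASE)
        for fam, pat in raw.get("complement_patterns", {}).items()
    }
    return RuleSet(
        version=int(raw.get("version", 0)),
        labels=labels,
        families=families,
        accessory=raw.get("accessory", {}),
        complement_patterns=complement,
        tir_labels=frozenset(raw["tir_equivalence"]),
        novelty_indicative=frozenset(raw["novelty_indicative"]),
        clan_map=load_clan_map(clan_map_path),
    )
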