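"""Count tables and presence/absence matrices.

Two counting conventions coexist, mirroring the twin table semantics of
comparative immunome surveys:

* conservative — genes (isoform groups) with at least one *complete* call:
  full ORF, homology support and the canonical domain set;
* non-conservative — genes with at least one call of any completeness,
  including partial ORFs.

Conserved candidate families report both; accessory families (CniFL, MASP,
SRCR, C-type lectin) are counted non-conservatively; complement components
are presence/absence flags only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable

import pandas as pd

from .records import (
    ACCESSORY_FAMILIES,
    CANDIDATE_FAMILIES,
    COMPLEMENT_FAMILIES,
    NOVEL_PATTERNS,
    FamilyCall,
    NoveltyCall,
)


@dataclass
class FamilyCounts:
    n_complete_genes: int = 0
    n_total_genes: int = 0
    n_isoforms: int = 0
    n_partial_genes: int = 0  # genes with calls but no complete call


@dataclass
class CountsReport:
    """Per-species family counts, subtype tallies and presence flags."""

    species_label: str
    families: dict[str, FamilyCounts] = field(default_factory=dict)
    novelty: dict[str, int] = field(default_factory=dict)  # pattern -> n genes
    presence: dict[str, bool] = field(default_factory=dict)
    n_membrane_nlr: int = 0          # incl. partial NLRs, clustered helices
    n_cnifl_with_wap: int = 0
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for fam, c in self.families.items():
            if c.n_complete_genes > c.n_total_genes:
                raise AssertionError(f"{fam}: complete > total")
            if c.n_total_genes and c.n_isoforms < c.n_total_genes:
                raise AssertionError(f"{fam}: fewer isoforms than genes")


def build_counts(
    calls: Iterable[FamilyCall],
    novelty_calls: Iterable[NoveltyCall] = (),
    gene_groups: dict[str, str] | Callable[[str], str] | None = None,
    species_label: str = "unknown",
    presence: dict[str, bool] | None = None,
) -> CountsReport:
    """Aggregate calls into a per-species CountsReport.

    ``gene_groups`` maps transcript_id -> gene_group_id (dict or callable);
    a call whose transcript has no mapping is an error.
    """
    if gene_groups is None:
        lookup = lambda tx: tx
    elif callable(gene_groups):
        lookup = gene_groups
    else:
        def lookup(tx: str) -> str:
            try:
                return gene_groups[tx]
            except KeyError:
                raise KeyError(f"call for {tx!r} has no gene group") from None

    by_family: dict[str, dict[str, list[FamilyCall]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for call in calls:
        by_family[call.family][lookup(call.transcript_id)].append(call)

    report = CountsReport(species_label=species_label)
    for fam in (*CANDIDATE_FAMILIES, *ACCESSORY_FAMILIES):
        groups = by_family.get(fam, {})
        complete = {
            g for g, cs in groups.items()
            if any(c.completeness == "complete" for c in cs)
        }
        counts = FamilyCounts(
            n_complete_genes=len(complete),
            n_total_genes=len(groups),
            n_isoforms=sum(len(cs) for cs in groups.values()),
            n_partial_genes=len(groups) - len(complete),
        )
        report.families[fam] = counts

    # membrane-NLR tally includes partial NLRs by design
    nlr_calls = [c for cs in by_family.get("NLR", {}).values() for c in cs]
    report.n_membrane_nlr = len(
        {
            lookup(c.transcript_id)
            for c in nlr_calls
            if c.membrane_bound and c.tmd_n_terminal_clustered
        }
    )
    report.n_cnifl_with_wap = len(
        {
            lookup(c.transcript_id)
            for cs in by_family.get("CniFL", {}).values()
            for c in cs
            if c.has_wap
        }
    )

    nov_groups: dict[str, set] = defaultdict(set)
    for nc in novelty_calls:
        nov_groups[nc.pattern].add(lookup(nc.transcript_id))
    report.novelty = {pat: len(nov_groups.get(pat, ())) for pat in NOVEL_PATTERNS}

    report.presence = dict(presence or {fam: False for fam in COMPLEMENT_FAMILIES})
    report.validate()
    return report


def merge_species(reports: list[CountsReport]) -> pd.DataFrame:
    """Stack per-species reports into a species x family matrix.

    Row order follows input order; families absent from a report appear as
    zeros; duplicate species labels are an error.  Candidate families get
    ``<fam>_complete``/``<fam>_total`` columns, accessory families a single
    non-conservative count, complement families a +/- flag.
    """
    labels = [r.species_label for r in reports]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels")
    rows = []
    for r in reports:
        row: dict[str, object] = {"species": r.species_label}
        for fam in CANDIDATE_FAMILIES:
            c = r.families.get(fam, FamilyCounts())
            row[f"{fam}_complete"] = c.n_complete_genes
            row[f"{fam}_total"] = c.n_total_genes
        for fam in ACCESSORY_FAMILIES:
            row[fam] = r.families.get(fam, FamilyCounts()).n_total_genes
        for fam in COMPLEMENT_FAMILIES:
            row[fam] = "+" if r.presence.get(fam, False) else "-"
        for pat in NOVEL_PATTERNS:
            row[f"novel_{pat}"] = r.novelty.get(pat, 0)
        row["membrane_NLR"] = r.n_membrane_nlr
        row["CniFL_with_WAP"] = r.n_cnifl_with_wap
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")


def write_tables(matrix: pd.DataFrame, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(outdir / "counts.tsv", sep="\t")
    matrix.to_json(outdir / "counts.json", orient="index", indent=1)
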