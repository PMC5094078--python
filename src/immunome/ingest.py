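"""Readers for standard annotation artifacts and catalog assembly.

The pipeline does not run HMMER/BLAST/TMHMM/TransDecoder itself; it consumes
their tabular outputs:

* domain hits — HMMER ``domtblout`` (hmmscan orientation: target = domain
  model, query = transcript) or a 7-column TSV
  ``transcript_id  domain_name  family_accession  clan_accession  aa_start
  aa_end  e_value``;
* transmembrane helices — TMHMM v2 "short" one-line-per-protein format, or a
  3-column TSV ``transcript_id  aa_start  aa_end``;
* homology — BLAST tabular (outfmt 6, 12 columns; an optional 13th column
  carries the subject species);
* ORFs — peptide FASTA with TransDecoder-style ``type:`` tags, with an
  optional matching CDS FASTA.

All amino-acid coordinates are 1-based inclusive envelope coordinates.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from collections import defaultdict
from pathlib import Path
from typing import Callable, Iterable, Optional

from Bio import SeqIO

from .records import (
    DomainHit,
    HomologyHit,
    OrfRecord,
    TmdSegment,
    TranscriptAnnotation,
    default_gene_group,
)

log = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 1e-5  # mirrors the BLAST retention threshold


class IngestError(ValueError):
    """Malformed input row; message names the file and line number."""


def _parse_fail(path, lineno: int, why: str) -> IngestError:
    return IngestError(f"{path}:{lineno}: {why}")


# --- domain hits ------------------------------------------------------------

def read_domain_hits(
    path: str | Path,
    e_value_max: float = DEFAULT_EVALUE_MAX,
    dialect: str = "tsv",
) -> list[DomainHit]:
    """Read domain hits, excluding rows with E-value above ``e_value_max``.

    Rows are returned in file order.  ``dialect`` is ``"tsv"`` (7 columns)
    or ``"domtblout"`` (HMMER; the independent-domain i-Evalue and envelope
    coordinates are used, the clan column is left empty).
    """
    if dialect not in ("tsv", "domtblout"):
        raise ValueError(f"unknown domain-hit dialect {dialect!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                if dialect == "tsv":
                    cols = line.split("\t")
                    if len(cols) != 7:
                        raise ValueError(f"expected 7 columns, got {len(cols)}")
                    tx, name, fam, clan, start, end, ev = cols
                else:  # domtblout
                    cols = line.split()
                    if len(cols) < 22:
                        raise ValueError(f"expected >=22 columns, got {len(cols)}")
                    name = cols[0]
                    fam = cols[1].split(".")[0]
                    if fam in ("-", ""):
                        fam = ""
                    tx, clan = cols[3], ""
                    ev, start, end = cols[12], cols[19], cols[20]
                hit = DomainHit(
                    transcript_id=tx.strip(),
                    domain_name=name.strip(),
                    family_accession=fam.strip(),
                    clan_accession=clan.strip(),
                    aa_start=int(start),
                    aa_end=int(end),
                    e_value=float(ev),
                )
            except (ValueError, IndexError) as exc:
                raise _parse_fail(path, lineno, str(exc)) from exc
            if hit.e_value <= e_value_max:
                hits.append(hit)
    return hits


# --- transmembrane segments -------------------------------------------------

_TMHMM_TOPO = re.compile(r"[io](\d+)-(\d+)")


def read_tmd_calls(path: str | Path) -> dict[str, list[TmdSegment]]:
    """Read TMHMM-short or 3-column TSV helix calls.

    Only predicted helices become segments (``PredHel=0`` rows contribute
    nothing); per-transcript segments are sorted by start coordinate.
    Overlapping segments on one transcript are kept but draw a warning.
    """
    segments: dict[str, list[TmdSegment]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if any(c.startswith("Topology=") for c in cols):
                    tx = cols[0].strip()
                    topo = next(c for c in cols if c.startswith("Topology="))
                    for m in _TMHMM_TOPO.finditer(topo[len("Topology="):]):
                        segments[tx].append(
                            TmdSegment(tx, int(m.group(1)), int(m.group(2)))
                        )
                elif len(cols) == 3:
                    tx = cols[0].strip()
                    segments[tx].append(TmdSegment(tx, int(cols[1]), int(cols[2])))
                elif any("PredHel=" in c for c in cols):
                    continue  # short-format row with zero helices
                else:
                    raise ValueError("not TMHMM-short or 3-column TSV")
            except (ValueError, StopIteration) as exc:
                raise _parse_fail(path, lineno, str(exc)) from exc
    out: dict[str, list[TmdSegment]] = {}
    for tx, segs in segments.items():
        segs = sorted(segs, key=lambda s: (s.aa_start, s.aa_end))
        for a, b in zip(segs, segs[1:]):
            if b.aa_start <= a.aa_end:
                warnings.warn(f"overlapping TMD segments on {tx}; kept as-is")
        out[tx] = segs
    return out


# --- homology ---------------------------------------------------------------

DEFAULT_SPECIES_REGEX = re.compile(r"OS=([^|]+)$")


def read_homology(
    path: str | Path,
    database_label: str,
    e_value_max: float = DEFAULT_EVALUE_MAX,
    query_level: str = "peptide",
    species_regex: re.Pattern | str = DEFAULT_SPECIES_REGEX,
) -> list[HomologyHit]:
    """Read a 12-column BLAST tabular file for one database label.

    Retains only hits with E-value at or below ``e_value_max`` and orders
    them best-hit-first per transcript.  The subject species comes from an
    optional 13th column, falling back to ``species_regex`` applied to the
    subject id (default: a trailing ``OS=<species>`` tag).
    """
    if isinstance(species_regex, str):
        species_regex = re.compile(species_regex)
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise _parse_fail(path, lineno, f"expected >=12 columns, got {len(cols)}")
            try:
                e_value = float(cols[10])
            except ValueError as exc:
                raise _parse_fail(path, lineno, f"bad E-value {cols[10]!r}") from exc
            if e_value > e_value_max:
                continue
            subject = cols[1]
            if len(cols) >= 13 and cols[12].strip():
                species = cols[12].strip()
            else:
                m = species_regex.search(subject)
                species = m.group(1).strip() if m else ""
            hits.append(
                HomologyHit(
                    transcript_id=cols[0],
                    database_label=database_label,
                    subject_id=subject,
                    subject_species=species,
                    e_value=e_value,
                    query_level=query_level,
                )
            )
    hits.sort(key=lambda h: (h.transcript_id, h.e_value))
    return hits


# --- ORFs -------------------------------------------------------------------

_ORF_TYPE = re.compile(r"type:(\S+)")
_COMPLETENESS = {
    "complete": (True, True),
    "5prime_partial": (False, True),
    "3prime_partial": (True, False),
    "internal": (False, False),
}


def read_orfs(
    pep_path: str | Path,
    cds_path: str | Path | None = None,
    transcript_of: Callable[[str], str] | None = None,
) -> list[OrfRecord]:
    """Read ORFs from a peptide FASTA (TransDecoder-style ``type:`` tags).

    When the header carries no completeness tag, completeness is inferred
    from the peptide: a leading methionine marks the start, a trailing ``*``
    the stop (the marker is removed from the stored peptide).
    ``transcript_of`` maps orf id to transcript id (default: strip a
    trailing ``.p<n>`` suffix).
    """
    if transcript_of is None:
        transcript_of = lambda orf_id: re.sub(r"\.p\d+$", "", orf_id)
    cds_by_id: dict[str, str] = {}
    if cds_path is not None:
        cds_by_id = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_path), "fasta")
        }
    orfs: list[OrfRecord] = []
    for rec in SeqIO.parse(str(pep_path), "fasta"):
        pep = str(rec.seq)
        m = _ORF_TYPE.search(rec.description)
        if m:
            try:
                has_start, has_stop = _COMPLETENESS[m.group(1)]
            except KeyError:
                raise IngestError(f"unknown ORF type {m.group(1)!r} on {rec.id}")
            pep = pep.rstrip("*")
        else:
            has_start = pep.startswith("M")
            has_stop = pep.endswith("*")
            pep = pep.rstrip("*")
        orfs.append(
            OrfRecord(
                transcript_id=transcript_of(rec.id),
                orf_id=rec.id,
                peptide=pep,
                has_start_codon=has_start,
                has_stop_codon=has_stop,
                coding_sequence=cds_by_id.get(rec.id),
            )
        )
    return orfs


# --- assembly ---------------------------------------------------------------

def assemble_annotations(
    orfs: Iterable[OrfRecord],
    domains: Iterable[DomainHit] = (),
    tmds: dict[str, list[TmdSegment]] | None = None,
    homology: Iterable[HomologyHit] = (),
    species_label: str = "unknown",
    grouping_rule: Callable[[str], str] = default_gene_group,
) -> tuple[list[TranscriptAnnotation], list[str]]:
    """Merge per-source records into one TranscriptAnnotation per ORF.

    Returns ``(annotations, warnings)``.  Orphan domain/TMD/homology rows
    (no matching ORF) are dropped with a warning; a duplicate orf_id is an
    error.
    """
    orfs = list(orfs)
    seen: set[str] = set()
    for orf in orfs:
        if orf.orf_id in seen:
            raise IngestError(f"duplicate orf_id {orf.orf_id!r}")
        seen.add(orf.orf_id)
    tx_ids = {o.transcript_id for o in orfs}

    dom_by_tx: dict[str, list[DomainHit]] = defaultdict(list)
    for d in domains:
        dom_by_tx[d.transcript_id].append(d)
    hom_by_tx: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in homology:
        hom_by_tx[h.transcript_id].append(h)
    tmds = tmds or {}

    warns: list[str] = []
    for source, keys in (
        ("domain", dom_by_tx), ("TMD", tmds), ("homology", hom_by_tx)
    ):
        for tx in sorted(set(keys) - tx_ids):
            warns.append(f"orphan {source} rows for unknown transcript {tx!r} dropped")

    annotations = [
        TranscriptAnnotation(
            transcript_id=o.transcript_id,
            gene_group_id=grouping_rule(o.transcript_id),
            species_label=species_label,
            orf=o,
            domains=list(dom_by_tx.get(o.transcript_id, [])),
            tmds=list(tmds.get(o.transcript_id, [])),
            homology=list(hom_by_tx.get(o.transcript_id, [])),
        )
        for o in orfs
    ]
    for w in warns:
        log.warning(w)
    return annotations, warns


# --- catalog serialisation --------------------------------------------------
# The canonical on-disk catalog is a directory of four TSVs plus catalog.json
# with the full structure; re-reading either representation round-trips.

def _ann_to_dict(a: TranscriptAnnotation) -> dict:
    return {
        "transcript_id": a.transcript_id,
        "gene_group_id": a.gene_group_id,
        "species_label": a.species_label,
        "orf": {
            "orf_id": a.orf.orf_id,
            "peptide": a.orf.peptide,
            "has_start_codon": a.orf.has_start_codon,
            "has_stop_codon": a.orf.has_stop_codon,
            "coding_sequence": a.orf.coding_sequence,
        },
        "domains": [
            [d.domain_name, d.family_accession, d.clan_accession,
             d.aa_start, d.aa_end, d.e_value]
            for d in a.domains
        ],
        "tmds": [[t.aa_start, t.aa_end] for t in a.tmds],
        "homology": [
            [h.database_label, h.subject_id, h.subject_species,
             h.e_value, h.query_level]
            for h in a.homology
        ],
    }


def _ann_from_dict(d: dict) -> TranscriptAnnotation:
    tx = d["transcript_id"]
    return TranscriptAnnotation(
        transcript_id=tx,
        gene_group_id=d["gene_group_id"],
        species_label=d["species_label"],
        orf=OrfRecord(
            transcript_id=tx,
            orf_id=d["orf"]["orf_id"],
            peptide=d["orf"]["peptide"],
            has_start_codon=d["orf"]["has_start_codon"],
            has_stop_codon=d["orf"]["has_stop_codon"],
            coding_sequence=d["orf"]["coding_sequence"],
        ),
        domains=[DomainHit(tx, *row[:3], int(row[3]), int(row[4]), float(row[5]))
                 for row in d["domains"]],
        tmds=[TmdSegment(tx, int(a), int(b)) for a, b in d["tmds"]],
        homology=[HomologyHit(tx, row[0], row[1], row[2], float(row[3]), row[4])
                  for row in d["homology"]],
    )


def write_catalog(catalog: list[TranscriptAnnotation], outdir: str | Path) -> Path:
    """Write the merged catalog (TSV set + catalog.json) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "catalog.json", "w") as fh:
        json.dump([_ann_to_dict(a) for a in catalog], fh, indent=1)

    with open(outdir / "orfs.tsv", "w") as fh:
        fh.write("transcript_id\torf_id\tgene_group_id\tspecies_label\t"
                 "has_start_codon\thas_stop_codon\tpeptide\tcoding_sequence\n")
        for a in catalog:
            o = a.orf
            fh.write("\t".join([
                a.transcript_id, o.orf_id, a.gene_group_id, a.species_label,
                str(int(o.has_start_codon)), str(int(o.has_stop_codon)),
                o.peptide, o.coding_sequence or "",
            ]) + "\n")
    with open(outdir / "domains.tsv", "w") as fh:
        fh.write("transcript_id\tdomain_name\tfamily_accession\t"
                 "clan_accession\taa_start\taa_end\te_value\n")
        for a in catalog:
            for d in a.domains:
                fh.write("\t".join([
                    d.transcript_id, d.domain_name, d.family_accession,
                    d.clan_accession, str(d.aa_start), str(d.aa_end),
                    repr(d.e_value),
                ]) + "\n")
    with open(outdir / "tmds.tsv", "w") as fh:
        fh.write("transcript_id\taa_start\taa_end\n")
        for a in catalog:
            for t in a.tmds:
                fh.write(f"{t.transcript_id}\t{t.aa_start}\t{t.aa_end}\n")
    with open(outdir / "homology.tsv", "w") as fh:
        fh.write("transcript_id\tdatabase_label\tsubject_id\t"
                 "subject_species\te_value\tquery_level\n")
        for a in catalog:
            for h in a.homology:
                fh.write("\t".join([
                    h.transcript_id, h.database_label, h.subject_id,
                    h.subject_species, repr(h.e_value), h.query_level,
                ]) + "\n")
    return outdir


def ingest_directory(
    indir: str | Path,
    species_label: str = "unknown",
    e_value_max: float = DEFAULT_EVALUE_MAX,
) -> tuple[list[TranscriptAnnotation], list[str]]:
    """Assemble a catalog from a standard fixture/annotation directory.

    Expects ``pep.fa`` (required) and optionally ``cds.fa``, ``domains.tsv``,
    ``tmhmm.txt`` and ``blast_<label>.tsv`` files.
    """
    indir = Path(indir)
    orfs = read_orfs(
        indir / "pep.fa",
        indir / "cds.fa" if (indir / "cds.fa").exists() else None,
    )
    domains = (
        read_domain_hits(indir / "domains.tsv", e_value_max)
        if (indir / "domains.tsv").exists()
        else []
    )
    tmds = (
        read_tmd_calls(indir / "tmhmm.txt")
        if (indir / "tmhmm.txt").exists()
        else {}
    )
    homology: list[HomologyHit] = []
    for blast in sorted(indir.glob("blast_*.tsv")):
        label = blast.stem.removeprefix("blast_")
        homology.extend(read_homology(blast, label, e_value_max))
    return assemble_annotations(
        orfs, domains, tmds, homology, species_label=species_label
    )


def read_catalog(path: str | Path) -> list[TranscriptAnnotation]:
    """Re-read a catalog directory (or a bare catalog.json file)."""
    path = Path(path)
    if path.is_dir():
        path = path / "catalog.json"
    with open(path) as fh:
        return [_ann_from_dict(d) for d in json.load(fh)]
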