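"""Synthetic annotated-transcriptome fixtures with planted ground truth.

The generator emulates the statistical structure of an assembled, annotated
actiniarian transcriptome as the pipeline consumes it: peptide/CDS FASTA,
Pfam-style domain hit tables, TMHMM-short transmembrane calls and BLAST
tabular homology tables, plus a truth table recording every planted label.
Peptides are concatenations of per-domain placeholder blocks whose
coordinates drive the domain table — no homology search is simulated, since
the pipeline consumes annotations rather than raw sequence similarity.

Planted content:

* the five conserved candidate families (TLR, MyD88, IL-1R-like, NF-κB,
  NLR) with configurable gene counts, isoform multiplicity and a fraction
  of partial ORFs; a configurable number of NLR genes are membrane-bound
  (3–5 helices clustered at the N-terminus), the rest cytosolic;
* accessory families (CniFL with optional WAP + TMD, MASP, SRCR, CTLD);
* decoy/novel architectures (RHD-only, TIR-only/DUF1863, NG1, NG2, NG3,
  unmatched-novel), annotated only against *N. vectensis* or not at all;
* complement homology-only transcripts driving presence/absence flags.

Everything emitted is a deterministic function of (config, seed).

A codon-pair simulator with a controlled nonsynonymous/synonymous rate
ratio exercises the dN/dS stage.
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .dnds import BASES, genetic_code, is_transition
from .records import DEATH_FOLDS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NVECTENSIS = "Nematostella vectensis"
MASP_REFERENCE_ID = "NVE_MASP1"

# (domain_name, family_accession, clan_accession, block length in aa)
_BLOCKS = {
    "TIR": ("TIR", "PF01582", "CL0173", 135),
    "TIR_2": ("TIR_2", "PF13676", "CL0173", 120),
    "DUF1863": ("DUF1863", "", "", 110),
    "LRR": ("LRR_8", "PF13855", "CL0022", 24),
    "Ig": ("I-set", "PF07679", "CL0011", 90),
    "RHD": ("RHD_DNA_bind", "PF00554", "CL0159", 170),
    "Ank": ("Ank", "PF00023", "CL0465", 33),
    "NACHT": ("NACHT", "PF05729", "CL0023", 190),
    "CARD": ("CARD", "PF00619", "CL0041", 90),
    "PYD": ("PYRIN", "PF02758", "CL0041", 90),
    "DD": ("Death", "PF00531", "CL0041", 90),
    "DED": ("DED", "PF01335", "CL0041", 85),
    "Collagen": ("Collagen", "PF01391", "CL0422", 60),
    "Fibrinogen": ("Fibrinogen_C", "PF00147", "CL0422", 220),
    "WAP": ("WAP", "PF00095", "CL0617", 50),
    "SRCR": ("SRCR", "PF00530", "CL0639", 100),
    "Lectin_C": ("Lectin_C", "PF00059", "CL0056", 115),
    "CUB": ("CUB", "PF00431", "CL0164", 110),
    "EGF_CA": ("EGF_CA", "PF07645", "CL0001", 40),
    "Sushi": ("Sushi", "PF00084", "CL0500", 60),
    "Trypsin": ("Trypsin", "PF00089", "CL0124", 220),
    "Pkinase": ("Pkinase", "PF00069", "CL0016", 250),
    "Pkinase_Tyr": ("Pkinase_Tyr", "PF07714", "CL0016", 250),
    "Ras": ("Ras", "PF00071", "CL0023", 160),
    "Miro": ("Miro", "PF08477", "CL0023", 120),
    "COR": ("COR", "", "", 90),
    "BTK": ("BTK", "PF00779", "", 80),
    "SH3": ("SH3_1", "PF00018", "CL0010", 55),
    "SAM": ("SAM_1", "PF00536", "CL0003", 65),
}

DECOY_KINDS = ("RHD_only", "TIR_only", "NG1", "NG2", "NG3", "unmatched_novel")


@dataclass
class FixtureConfig:
    """Planted gene counts, noise levels and layout of one species fixture."""

    species_label: str = "A_synthetica_1"
    family_genes: dict[str, int] = field(
        default_factory=lambda: {
            "TLR": 3, "MyD88": 3, "IL1R_like": 3, "NFKB": 3, "NLR": 3,
            "CniFL": 3, "MASP": 3, "SRCR": 3, "CTLD": 3,
        }
    )
    decoys: dict[str, int] = field(
        default_factory=lambda: {k: 2 for k in DECOY_KINDS if k != "unmatched_novel"}
    )
    isoform_weights: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3) isoforms
    fraction_partial: float = 0.3
    fraction_missing_homology: float = 0.0
    n_membrane_nlr: int = 1        # of the NLR genes; 3-5 N-terminal helices
    cnifl_wap_fraction: float = 0.33
    complement_present: tuple[str, ...] = ("C3", "FactorB")
    n_complement_transcripts: int = 2

    def __post_init__(self) -> None:
        if any(n < 0 for n in {**self.family_genes, **self.decoys}.values()):
            raise ValueError("negative planted counts")
        for f in (self.fraction_partial, self.fraction_missing_homology):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.n_membrane_nlr > self.family_genes.get("NLR", 0):
            raise ValueError("more membrane NLRs than NLR genes")


@dataclass
class TruthRecord:
    transcript_id: str
    gene_group_id: str
    label: str              # family, decoy/novelty label
    completeness: str       # complete | partial
    membrane: bool
    n_tmd: int


@dataclass
class TruthTable:
    records: dict[str, TruthRecord] = field(default_factory=dict)
    complement_present: tuple[str, ...] = ()
    masp_reference_ids: tuple[str, ...] = (MASP_REFERENCE_ID,)

    def add(self, rec: TruthRecord) -> None:
        self.records[rec.transcript_id] = rec

    def by_label(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records.values():
            out.setdefault(r.label, set()).add(r.transcript_id)
        return out


# --- architecture layout ----------------------------------------------------

def _architecture(kind: str, rng: random.Random) -> tuple[list[str], int, bool]:
    """(domain block labels N->C, n_tmds, tmd_n_terminal) for one gene."""
    if kind == "TLR":
        return ["LRR"] * rng.randint(3, 12) + ["TIR"], 1, False
    if kind == "MyD88":
        return ["DD", "TIR"], 0, False
    if kind == "IL1R_like":
        return ["Ig"] * rng.randint(1, 3) + ["TIR"], 1, False
    if kind == "NFKB":
        return ["RHD"] + ["Ank"] * rng.randint(3, 6), 0, False
    if kind == "NLR":
        head = [rng.choice(DEATH_FOLDS)] if rng.random() < 0.5 else []
        return head + ["NACHT"] + ["LRR"] * rng.randint(3, 8), 0, False
    if kind == "CniFL":
        return ["Collagen", "Ig", "Ig", "Ig", "Fibrinogen"], 1, False
    if kind == "MASP":
        return ["CUB", "EGF_CA", "CUB", "Sushi", "Sushi", "Trypsin"], 0, False
    if kind == "SRCR":
        return ["SRCR"] * rng.randint(1, 3), 0, False
    if kind == "CTLD":
        return ["Lectin_C"], 0, False
    if kind == "RHD_only":
        return ["RHD"], 0, False
    if kind == "TIR_only":
        return [rng.choice(["TIR_2", "DUF1863"])], 0, False
    if kind == "NG1":
        return ["LRR", "Miro", "Ras", "COR", "TIR_2"], 0, False
    if kind == "NG2":
        return ["TIR_2"] * rng.randint(1, 2) + ["BTK"], 0, False
    if kind == "NG3":
        arch = ["Pkinase", "DD", "TIR"]
        if rng.random() < 0.5:
            arch.insert(1, "SH3")
        return arch, 0, False
    if kind == "unmatched_novel":
        return ["TIR_2", "SAM"], 0, False
    raise ValueError(f"unknown planted kind {kind!r}")


_CANDIDATES = {"TLR", "MyD88", "IL1R_like", "NFKB", "NLR"}
_NOVELTY = {"TIR_only", "NG1", "NG2", "NG3", "unmatched_novel"}


def _random_peptide(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def _reverse_translate(pep: str, rng: random.Random, code: dict[str, str]) -> str:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(code.items()):
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    return "".join(rng.choice(by_aa[aa]) for aa in pep)


@dataclass
class _Transcript:
    tx_id: str
    gene_group: str
    kind: str
    peptide: str
    cds: str
    orf_type: str
    domains: list[tuple]            # (name, fam, clan, start, end, evalue)
    tmds: list[tuple[int, int]]
    homology: list[tuple]           # (db, subject, species, evalue)
    truth: TruthRecord


def _build_transcript(
    tx_id: str,
    gene_group: str,
    kind: str,
    arch: list[str],
    n_tmd_planted: int,
    rng: random.Random,
    partial: bool,
    missing_homology: bool,
    membrane_nlr: bool,
    has_wap: bool,
    code: dict[str, str],
) -> _Transcript:
    blocks = list(arch)
    if has_wap:
        blocks.append("WAP")

    # Lay domain blocks down with random linkers; leading M + signal stub.
    pieces = ["M" + _random_peptide(rng, rng.randint(8, 20))]
    pos = len(pieces[0])
    tmds: list[tuple[int, int]] = []

    if membrane_nlr:
        # 3-5 helices clustered at the N-terminus: midpoints well inside
        # the first quarter of a peptide that continues with NACHT+LRRs.
        for _ in range(rng.randint(3, 5)):
            helix = _random_peptide(rng, 21)
            gap = _random_peptide(rng, rng.randint(3, 8))
            tmds.append((pos + len(gap) + 1, pos + len(gap) + 21))
            pieces.append(gap + helix)
            pos += len(gap) + 21

    domains: list[tuple] = []
    for i, label in enumerate(blocks):
        name, fam, clan, length = _BLOCKS[label]
        linker = _random_peptide(rng, rng.randint(5, 25))
        start = pos + len(linker) + 1
        end = start + length - 1
        # the single C-terminal-side TMD of TLR/IL-1R/CniFL sits just before
        # the last (cytosolic) block
        if n_tmd_planted == 1 and i == len(arch) - 1:
            helix = _random_peptide(rng, 21)
            tmds.append((pos + len(linker) + 1, pos + len(linker) + 21))
            linker = linker + helix + _random_peptide(rng, 5)
            start = pos + len(linker) + 1
            end = start + length - 1
        block_pep = _random_peptide(rng, length)
        pieces.append(linker + block_pep)
        pos = end
        e_value = 10 ** -rng.uniform(8, 40)
        domains.append((name, fam, clan, start, end, e_value))
        if kind == "NG3" and label == "Pkinase":
            # kinase models always co-fire on the same segment
            name2, fam2, clan2, _ = _BLOCKS["Pkinase_Tyr"]
            domains.append((name2, fam2, clan2, start + 3, end, e_value * 10))

    pieces.append(_random_peptide(rng, rng.randint(5, 30)))
    peptide = "".join(pieces)

    if membrane_nlr and tmds:
        # the planted geometry is "helices clustered at the N-terminus":
        # pad the C-terminal region until every helix midpoint sits within
        # the first quarter of the peptide
        max_mid = max((s + e) / 2 for s, e in tmds)
        min_len = int(max_mid / 0.25) + 1
        if len(peptide) < min_len:
            peptide += _random_peptide(rng, min_len - len(peptide))

    orf_type = "complete"
    if partial:
        orf_type = rng.choice(["5prime_partial", "3prime_partial", "internal"])
        if orf_type in ("5prime_partial", "internal"):
            peptide = peptide[1:]  # drop the planted start methionine
            domains = [(n, f, c, s - 1, e - 1, ev) for n, f, c, s, e, ev in domains]
            tmds = [(s - 1, e - 1) for s, e in tmds]

    cds = _reverse_translate(peptide, rng, code)
    if orf_type in ("complete", "5prime_partial"):
        cds += rng.choice(["TAA", "TAG", "TGA"])

    homology: list[tuple] = []
    if kind in _NOVELTY:
        status = rng.choice(["no_hits", "nvectensis_only"])
        if status == "nvectensis_only":
            homology.append(
                ("trembl", f"NVE_{rng.randint(1000, 9999)}", NVECTENSIS,
                 10 ** -rng.uniform(6, 20))
            )
    elif not missing_homology:
        subject = f"sp|P{rng.randint(10000, 99999)}|{kind.upper()[:6]}_MOUSE"
        homology.append(("swissprot", subject, "Mus musculus",
                         10 ** -rng.uniform(10, 60)))
        if kind == "MASP":
            homology.append(("trembl", MASP_REFERENCE_ID, NVECTENSIS,
                             10 ** -rng.uniform(20, 60)))

    if kind in _NOVELTY:
        completeness = "n/a"
    else:
        has_start = orf_type in ("complete", "3prime_partial")
        has_stop = orf_type in ("complete", "5prime_partial")
        canonical_ok = kind != "RHD_only"  # RHD without ankyrin: never complete
        complete = has_start and has_stop and bool(homology) and canonical_ok
        completeness = "complete" if complete else "partial"

    truth = TruthRecord(
        transcript_id=tx_id,
        gene_group_id=gene_group,
        label={"RHD_only": "NFKB"}.get(kind, kind),
        completeness=completeness,
        membrane=bool(tmds),
        n_tmd=len(tmds),
    )
    return _Transcript(
        tx_id=tx_id, gene_group=gene_group, kind=kind, peptide=peptide,
        cds=cds, orf_type=orf_type, domains=domains, tmds=tmds,
        homology=homology, truth=truth,
    )


def generate_fixture(
    config: FixtureConfig, seed: int, outdir: str | Path
) -> tuple[Path, TruthTable]:
    """Emit a complete fixture directory; byte-deterministic in (config, seed).

    Files: ``pep.fa``, ``cds.fa``, ``domains.tsv``, ``tmhmm.txt``,
    ``blast_swissprot.tsv``, ``blast_trembl.tsv``, ``truth.tsv`` and
    ``fixture_meta.json``.
    """
    rng = random.Random(seed)
    code = genetic_code(1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    transcripts: list[_Transcript] = []
    truth = TruthTable(complement_present=tuple(config.complement_present))
    gene_idx = 0

    def plant(kind: str, n_genes: int, membrane_flags: Iterable[bool]):
        nonlocal gene_idx
        for gi, membrane in zip(range(n_genes), membrane_flags):
            gene_idx += 1
            group = f"DN{gene_idx}_c0_g1"
            arch, n_tmd, _ = _architecture(kind, rng)
            has_wap = kind == "CniFL" and rng.random() < config.cnifl_wap_fraction
            weights = config.isoform_weights
            n_iso = rng.choices(range(1, len(weights) + 1), weights=weights)[0]
            for iso in range(1, n_iso + 1):
                partial = rng.random() < config.fraction_partial
                missing_hom = rng.random() < config.fraction_missing_homology
                tx = _build_transcript(
                    tx_id=f"{group}_i{iso}",
                    gene_group=group,
                    kind=kind,
                    arch=arch,
                    n_tmd_planted=n_tmd,
                    rng=rng,
                    partial=partial,
                    missing_homology=missing_hom,
                    membrane_nlr=membrane,
                    has_wap=has_wap,
                    code=code,
                )
                transcripts.append(tx)
                truth.add(tx.truth)

    for family, n in sorted(config.family_genes.items()):
        if family == "NLR":
            flags = [i < config.n_membrane_nlr for i in range(n)]
            rng.shuffle(flags)
            plant(family, n, flags)
        else:
            plant(family, n, [False] * n)
    for decoy, n in sorted(config.decoys.items()):
        plant(decoy, n, [False] * n)

    # complement homology-only transcripts (no domains): drive presence flags
    complement_subject = {
        "C3": "sp|P01024|Complement_C3", "FactorB": "sp|P00751|Factor_B_CFAB",
        "C6": "sp|P13671|Complement_C6", "FactorI": "sp|P05156|Factor_I_CFAI",
    }
    for fam in sorted(config.complement_present):
        for k in range(config.n_complement_transcripts):
            gene_idx += 1
            group = f"DN{gene_idx}_c0_g1"
            tx_id = f"{group}_i1"
            pep = "M" + _random_peptide(rng, rng.randint(150, 400))
            transcripts.append(
                _Transcript(
                    tx_id=tx_id, gene_group=group, kind=f"complement_{fam}",
                    peptide=pep, cds=_reverse_translate(pep, rng, code) + "TAA",
                    orf_type="complete", domains=[], tmds=[],
                    homology=[("swissprot", complement_subject[fam],
                               "Homo sapiens", 10 ** -rng.uniform(8, 30))],
                    truth=TruthRecord(tx_id, group, f"complement_{fam}",
                                      "n/a", False, 0),
                )
            )
            truth.add(transcripts[-1].truth)

    _write_fixture_files(transcripts, truth, config, outdir)
    return outdir, truth


def _write_fixture_files(transcripts, truth: TruthTable, config, outdir: Path) -> None:
    with open(outdir / "pep.fa", "w") as fh:
        for t in transcripts:
            fh.write(f">{t.tx_id}.p1 type:{t.orf_type} len:{len(t.peptide)}\n")
            fh.write(t.peptide + "\n")
    with open(outdir / "cds.fa", "w") as fh:
        for t in transcripts:
            fh.write(f">{t.tx_id}.p1 type:{t.orf_type}\n{t.cds}\n")
    with open(outdir / "domains.tsv", "w") as fh:
        for t in transcripts:
            for name, fam, clan, s, e, ev in t.domains:
                fh.write(f"{t.tx_id}\t{name}\t{fam}\t{clan}\t{s}\t{e}\t{ev:.3e}\n")
    with open(outdir / "tmhmm.txt", "w") as fh:
        for t in transcripts:
            n = len(t.tmds)
            topo_str = "o" + "".join(
                f"{s}-{e}{'i' if k % 2 == 0 else 'o'}"
                for k, (s, e) in enumerate(t.tmds)
            )
            fh.write(
                f"{t.tx_id}\tlen={len(t.peptide)}\tExpAA={21 * n:.2f}\t"
                f"First60=0.00\tPredHel={n}\tTopology={topo_str if n else 'o'}\n"
            )
    for db in ("swissprot", "trembl"):
        with open(outdir / f"blast_{db}.tsv", "w") as fh:
            for t in transcripts:
                for dbl, subject, species, ev in t.homology:
                    if dbl != db:
                        continue
                    fh.write(
                        f"{t.tx_id}\t{subject}\t55.0\t200\t90\t0\t1\t200\t1\t200\t"
                        f"{ev:.3e}\t250\t{species}\n"
                    )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("transcript_id\tgene_group_id\tlabel\tcompleteness\t"
                 "membrane\tn_tmd\n")
        for t in transcripts:
            r = t.truth
            fh.write(f"{r.transcript_id}\t{r.gene_group_id}\t{r.label}\t"
                     f"{r.completeness}\t{int(r.membrane)}\t{r.n_tmd}\n")
    with open(outdir / "fixture_meta.json", "w") as fh:
        json.dump(
            {
                "species_label": config.species_label,
                "complement_present": sorted(config.complement_present),
                "masp_reference_ids": list(truth.masp_reference_ids),
                "config": dataclasses.asdict(config),
            },
            fh, indent=1, sort_keys=True,
        )


def load_truth(path: str | Path) -> TruthTable:
    path = Path(path)
    if path.is_dir():
        meta = json.loads((path / "fixture_meta.json").read_text())
        table = TruthTable(
            complement_present=tuple(meta["complement_present"]),
            masp_reference_ids=tuple(meta["masp_reference_ids"]),
        )
        path = path / "truth.tsv"
    else:
        table = TruthTable()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            tx, group, label, comp, mem, n_tmd = line.rstrip("\n").split("\t")
            table.add(TruthRecord(tx, group, label, comp, bool(int(mem)), int(n_tmd)))
    return table


# --- codon-pair simulator ---------------------------------------------------

@dataclass
class SimulatedPair:
    seq_a: str
    seq_b: str
    true_Nd: int      # nonsynonymous substitution events applied
    true_Sd: int
    n_codons: int
    omega_target: float
    kappa: float


def generate_codon_pair(
    omega_target: float,
    n_codons: int,
    kappa: float = 2.0,
    seed: int = 0,
    t: float = 0.3,
) -> SimulatedPair:
    """Evolve a descendant from a uniform-sense-codon ancestor.

    Single-nucleotide events are drawn with relative rates
    ``(kappa if transition) x (omega_target if nonsynonymous)``; changes
    creating stop codons are forbidden.  ``t`` is the expected number of
    applied substitution events per codon.  The realised synonymous and
    nonsynonymous event counts are recorded as ground truth.
    """
    if omega_target <= 0:
        raise ValueError("omega_target must be positive")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = random.Random(seed)
    code = genetic_code(1)
    sense = sorted(c for c, aa in code.items() if aa != "*")
    ancestor = [rng.choice(sense) for _ in range(n_codons)]
    descendant = list(ancestor)

    # per-codon table of legal changes: codon -> ([(mutant, syn, w)], total w)
    changes_of: dict[str, tuple[list[tuple[str, bool, float]], float]] = {}
    for codon in sense:
        aa = code[codon]
        lst = []
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1:]
                if code[mutant] == "*":
                    continue
                syn = code[mutant] == aa
                w = (kappa if is_transition(codon[pos], b) else 1.0) * (
                    1.0 if syn else omega_target
                )
                lst.append((mutant, syn, w))
        changes_of[codon] = (lst, sum(w for _, _, w in lst))

    # Poissonised event count at rate t per codon (inverse-CDF draw keeps
    # determinism tied to the single Random stream)
    lam = t * n_codons
    u, k = rng.random(), 0
    p = cum = math.exp(-lam)
    while u > cum and k < 10 * (int(lam) + 10):
        k += 1
        p *= lam / k
        cum += p
    n_events = k

    true_Sd = true_Nd = 0
    site_weights = [changes_of[c][1] for c in descendant]
    for _ in range(n_events):
        ci = rng.choices(range(n_codons), weights=site_weights)[0]
        options, _total = changes_of[descendant[ci]]
        mutant, syn, _w = rng.choices(options, weights=[w for *_, w in options])[0]
        descendant[ci] = mutant
        site_weights[ci] = changes_of[mutant][1]
        if syn:
            true_Sd += 1
        else:
            true_Nd += 1

    return SimulatedPair(
        seq_a="".join(ancestor),
        seq_b="".join(descendant),
        true_Nd=true_Nd,
        true_Sd=true_Sd,
        n_codons=n_codons,
        omega_target=omega_target,
        kappa=kappa,
    )


# --- recovery scoring -------------------------------------------------------

def score_recovery(
    truth: TruthTable, calls_by_transcript: dict[str, str]
) -> dict[str, dict[str, float]]:
    """Per-label precision/recall of predicted labels against the truth.

    ``calls_by_transcript`` maps transcript_id -> predicted label; absent
    transcripts count as negatives.  A call for a transcript missing from
    the truth table is an error.  Precision is NaN ("NA") when a label was
    never predicted.
    """
    unknown = set(calls_by_transcript) - set(truth.records)
    if unknown:
        raise KeyError(f"calls for transcripts absent from truth: {sorted(unknown)}")
    labels = {r.label for r in truth.records.values()} | set(
        calls_by_transcript.values()
    )
    out: dict[str, dict[str, float]] = {}
    for label in sorted(labels):
        tp = sum(
            1 for tx, lab in calls_by_transcript.items()
            if lab == label and truth.records[tx].label == label
        )
        fp = sum(
            1 for tx, lab in calls_by_transcript.items()
            if lab == label and truth.records[tx].label != label
        )
        fn = sum(
            1 for tx, r in truth.records.items()
            if r.label == label and calls_by_transcript.get(tx) != label
        )
        precision = tp / (tp + fp) if tp + fp else math.nan
        recall = tp / (tp + fn) if tp + fn else math.nan
        out[label] = {"precision": precision, "recall": recall,
                      "tp": tp, "fp": fp, "fn": fn}
    return out
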