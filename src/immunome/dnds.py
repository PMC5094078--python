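"""Pairwise dN/dS estimation on codon alignments.

The primary estimator is the Nei–Gojobori (1986) site-counting method:
synonymous/nonsynonymous site fractions per codon position, difference
counts averaged uniformly over all minimal substitution pathways that avoid
stop codons, and a Jukes–Cantor-style multiple-hit correction
``d = -3/4 · ln(1 - 4p/3)``.  A transition/transversion-aware variant
("yn00" mode) follows the Yang–Nielsen (2000) idea of weighting mutational
opportunities by an estimated kappa when counting sites, which removes the
main bias of equal-rate counting under transition bias.

Per-gene summaries average dN and dS (and their standard errors) over all
pairwise comparisons and report omega as the ratio of means — the average
ratio deliberately ignores the standard errors.  omega < 1 indicates
purifying selection, ≈ 1 neutrality, > 1 positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "PairwiseDnDs",
    "GeneDnDs",
    "strip_stops_and_validate",
    "pairwise_dnds",
    "gene_average",
    "classify_regime",
    "codon_sites",
    "codon_pair_differences",
]

BASES = "TCAG"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def genetic_code(table_id: int = 1) -> dict[str, str]:
    """Codon -> amino acid (stop codons map to '*')."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


# --- alignment container ----------------------------------------------------

@dataclass
class CodonAlignment:
    """An in-frame codon alignment (equal lengths, no internal stops)."""

    sequences: list[tuple[str, str]]
    gap_chars: str = "-N"

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0][1]) // 3 if self.sequences else 0

    def codons(self, index: int) -> list[str]:
        _, seq = self.sequences[index]
        return [seq[i: i + 3] for i in range(0, len(seq), 3)]

    @classmethod
    def from_fasta(cls, path: str | Path, **kw) -> "CodonAlignment":
        from Bio import SeqIO

        seqs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        return cls(strip_stops_and_validate([s for s in seqs]), **kw)

    @classmethod
    def from_phylip(cls, path: str | Path, **kw) -> "CodonAlignment":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "phylip-sequential")
        seqs = [(r.id, str(r.seq).upper()) for r in aln]
        return cls(strip_stops_and_validate(seqs), **kw)


def strip_stops_and_validate(
    sequences: Sequence[tuple[str, str]], table_id: int = 1
) -> list[tuple[str, str]]:
    """Remove terminal stop codons and reject frame problems.

    Each sequence must be a multiple of three long; a terminal stop codon is
    trimmed, an internal stop raises (it signals a frameshift or wrong
    frame).  Sequences are uppercased.
    """
    code = genetic_code(table_id)
    out: list[tuple[str, str]] = []
    for name, seq in sequences:
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
        codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
        if codons and code.get(codons[-1]) == "*":
            codons = codons[:-1]
        for i, codon in enumerate(codons):
            if code.get(codon) == "*":
                raise ValueError(f"{name}: internal stop codon {codon} at codon {i + 1}")
        out.append((name, "".join(codons)))
    lengths = {len(s) for _, s in out}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal codon counts after stripping: "
                         f"{sorted(n // 3 for n in lengths)}")
    return out


# --- site and difference counting ------------------------------------------

def codon_sites(
    codon: str, code: dict[str, str], kappa: float = 1.0
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; sums to 3.

    Each position contributes one site, split by the (kappa-weighted)
    fraction of its three possible changes that are synonymous.  Changes to
    stop codons count as nonsynonymous, so the per-codon sum is exactly 3.
    """
    aa = code[codon]
    s = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for b in BASES:
            if b == codon[pos]:
                continue
            w = kappa if is_transition(codon[pos], b) else 1.0
            mutant = codon[:pos] + b + codon[pos + 1:]
            tot_w += w
            if code[mutant] == aa:  # stop mutants ('*' != aa) are nonsyn
                syn_w += w
        s += syn_w / tot_w
    return s, 3.0 - s


def codon_pair_differences(
    a: str, b: str, code: dict[str, str]
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged uniformly over all minimal substitution pathways that do not
    pass through a stop codon; if every pathway is blocked by stops, all
    pathways are used.
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> tuple[float, float] | None:
        syn = non = 0
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if code[nxt] == "*" and len(diff_pos) > 1:
                return None  # pathway through a stop codon
            if code[nxt] == code[cur] and code[cur] != "*":
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    results = [r for r in (walk(p) for p in permutations(diff_pos)) if r is not None]
    if not results:
        results = []
        for p in permutations(diff_pos):
            syn = non = 0
            cur = a
            for pos in p:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                if code[nxt] == code[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            results.append((syn, non))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


# --- pairwise estimator -----------------------------------------------------

@dataclass
class PairwiseDnDs:
    id_a: str
    id_b: str
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float           # NaN when saturated
    dS: float
    se_dN: float
    se_dS: float
    n_codons: int
    kappa: float = 1.0
    method: str = "NG86"

    @property
    def saturated(self) -> bool:
        return math.isnan(self.dN) or math.isnan(self.dS)

    @property
    def omega(self) -> float:
        if self.saturated or self.dS == 0:
            return math.nan if self.dN == 0 or self.saturated else math.inf
        return self.dN / self.dS


def _jc_correct(p: float, n_sites: float) -> tuple[float, float]:
    """Jukes–Cantor-style correction and delta-method SE; NaN when p >= 3/4."""
    if p >= 0.75:
        return math.nan, math.nan
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    if n_sites <= 0:
        return d, math.nan
    var_p = p * (1.0 - p) / n_sites
    se = math.sqrt(var_p) / (1.0 - 4.0 * p / 3.0)
    return d, se


def estimate_kappa(codons_a: list[str], codons_b: list[str], code: dict[str, str]) -> float:
    """Kimura-2P kappa from third positions of codons with conserved
    first-two positions and four-fold degenerate sites in both sequences.

    Falls back to 1.0 when the estimate is unusable (few sites, log-domain
    failure), which reduces the weighted counting to plain NG86.
    """

    def fourfold(codon: str) -> bool:
        aa = code[codon]
        return all(code[codon[:2] + b] == aa for b in BASES)

    n = ts = tv = 0
    for ca, cb in zip(codons_a, codons_b):
        if ca[:2] != cb[:2] or not (fourfold(ca) and fourfold(cb)):
            continue
        n += 1
        if ca[2] != cb[2]:
            if is_transition(ca[2], cb[2]):
                ts += 1
            else:
                tv += 1
    if n < 10 or ts + tv == 0:
        return 1.0
    P, Q = ts / n, tv / n
    try:
        alpha = -0.5 * math.log(1 - 2 * P - Q) + 0.25 * math.log(1 - 2 * Q)
        beta = -0.25 * math.log(1 - 2 * Q)
    except ValueError:
        return 1.0
    if beta <= 0 or alpha <= 0:
        return 1.0
    return alpha / beta


def _pair_stats(
    codons_a: list[str],
    codons_b: list[str],
    code: dict[str, str],
    kappa: float,
) -> tuple[float, float, float, float, int]:
    """Site and difference counts over compared (ungapped, unambiguous) codons."""
    S = N = Sd = Nd = 0.0
    n_cmp = 0
    valid = set(code)
    for ca, cb in zip(codons_a, codons_b):
        if ca not in valid or cb not in valid:
            continue  # gaps/ambiguity: codon skipped in both
        n_cmp += 1
        sa, na = codon_sites(ca, code, kappa)
        sb, nb = codon_sites(cb, code, kappa)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_pair_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd, n_cmp


def pairwise_dnds(
    aln: CodonAlignment,
    method: str = "NG86",
    genetic_code_id: int = 1,
) -> list[PairwiseDnDs]:
    """All pairwise dN/dS estimates for an alignment.

    ``method`` is ``"NG86"`` (equal mutation rates) or ``"yn00"``
    (kappa-weighted site counting, kappa estimated per pair from four-fold
    degenerate third positions).  Codons containing gaps or ambiguity in
    either member of a pair are skipped for that pair.
    """
    if method not in ("NG86", "yn00"):
        raise ValueError(f"unknown method {method!r}")
    if len(aln.sequences) < 2:
        raise ValueError("need at least two sequences")
    code = genetic_code(genetic_code_id)
    out: list[PairwiseDnDs] = []
    for i, j in combinations(range(len(aln.sequences)), 2):
        ca, cb = aln.codons(i), aln.codons(j)
        kappa = estimate_kappa(ca, cb, code) if method == "yn00" else 1.0
        S, N, Sd, Nd, n_cmp = _pair_stats(ca, cb, code, kappa)
        pS = Sd / S if S > 0 else 0.0
        pN = Nd / N if N > 0 else 0.0
        dS, se_dS = _jc_correct(pS, S)
        dN, se_dN = _jc_correct(pN, N)
        out.append(
            PairwiseDnDs(
                id_a=aln.sequences[i][0], id_b=aln.sequences[j][0],
                N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS,
                dN=dN, dS=dS, se_dN=se_dN, se_dS=se_dS,
                n_codons=n_cmp, kappa=kappa, method=method,
            )
        )
    return out


# --- per-gene averaging -----------------------------------------------------

@dataclass
class GeneDnDs:
    """Per-gene summary: means over pairs and the ratio-of-means omega."""

    gene_label: str
    mean_dN: float
    mean_dS: float
    mean_se_dN: float
    mean_se_dS: float
    omega: float            # mean_dN / mean_dS; inf/nan sentinels when degenerate
    regime: str             # purifying | neutral | positive | undefined
    n_pairs: int
    n_excluded_saturated: int = 0
    method: str = "NG86"
    warnings: list[str] = field(default_factory=list)


def classify_regime(omega: float, tol: float = 0.05) -> str:
    """purifying (omega < 1-tol), neutral (|omega-1| <= tol) or positive."""
    if math.isnan(omega) or math.isinf(omega):
        return "undefined"
    if omega < 1.0 - tol:
        return "purifying"
    if omega > 1.0 + tol:
        return "positive"
    return "neutral"


def gene_average(
    pairs: Iterable[PairwiseDnDs],
    gene_label: str = "gene",
    regime_tol: float = 0.05,
) -> GeneDnDs:
    """Average dN, dS and their SEs over all pairwise comparisons.

    omega is the ratio of the mean dN to the mean dS (NOT the mean of the
    per-pair ratios, and the standard errors play no part in it).  Pairs
    with a saturated correction are excluded with a warning; dS == 0 with
    dN > 0 yields an infinite omega and an undefined regime.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairwise estimates to average")
    usable = [p for p in pairs if not p.saturated]
    warns = []
    if len(usable) < len(pairs):
        warns.append(f"excluded {len(pairs) - len(usable)} saturated pair(s)")
    if not usable:
        return GeneDnDs(
            gene_label=gene_label, mean_dN=math.nan, mean_dS=math.nan,
            mean_se_dN=math.nan, mean_se_dS=math.nan, omega=math.nan,
            regime="undefined", n_pairs=0,
            n_excluded_saturated=len(pairs), method=pairs[0].method,
            warnings=warns + ["all pairs saturated"],
        )
    mean = lambda xs: sum(xs) / len(xs)
    m_dN = mean([p.dN for p in usable])
    m_dS = mean([p.dS for p in usable])
    if m_dS > 0:
        omega = m_dN / m_dS
    elif m_dN > 0:
        omega = math.inf
    else:
        omega = math.nan
    return GeneDnDs(
        gene_label=gene_label,
        mean_dN=m_dN,
        mean_dS=m_dS,
        mean_se_dN=mean([p.se_dN for p in usable]),
        mean_se_dS=mean([p.se_dS for p in usable]),
        omega=omega,
        regime=classify_regime(omega, regime_tol),
        n_pairs=len(usable),
        n_excluded_saturated=len(pairs) - len(usable),
        method=usable[0].method,
        warnings=warns,
    )


# --- tabular output ---------------------------------------------------------

def pairs_to_tsv(pairs: list[PairwiseDnDs], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tN\tS\tNd\tSd\tpN\tpS\tdN\tse_dN\tdS\tse_dS\t"
                 "omega\tn_codons\tkappa\tmethod\n")
        for p in pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.N:.6f}\t{p.S:.6f}\t{p.Nd:.6f}\t"
                f"{p.Sd:.6f}\t{p.pN:.6f}\t{p.pS:.6f}\t{p.dN:.6f}\t{p.se_dN:.6f}\t"
                f"{p.dS:.6f}\t{p.se_dS:.6f}\t{p.omega:.6f}\t{p.n_codons}\t"
                f"{p.kappa:.4f}\t{p.method}\n"
            )


def gene_summary_to_tsv(genes: list[GeneDnDs], path: str | Path) -> None:
    """One row per gene, in the dN (±SE) / dS (±SE) / dN/dS layout."""
    with open(path, "w") as fh:
        fh.write("gene\tdN\tse_dN\tdS\tse_dS\tomega\tregime\tn_pairs\tmethod\n")
        for g in genes:
            fh.write(
                f"{g.gene_label}\t{g.mean_dN:.4f}\t{g.mean_se_dN:.4f}\t"
                f"{g.mean_dS:.4f}\t{g.mean_se_dS:.4f}\t{g.omega:.4f}\t"
                f"{g.regime}\t{g.n_pairs}\t{g.method}\n"
            )
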