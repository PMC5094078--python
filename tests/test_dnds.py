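"""dN/dS estimation against an independent brute-force oracle.

The oracle enumerates all nine single-base mutants for site counting and
all minimal substitution pathways (recursively, avoiding stop codons) for
difference counting, translating with Biopython rather than the package's
code table — so agreement is a genuine cross-check.
"""

import math
import random

import pytest
from Bio.Seq import Seq

from immunome.dnds import (
    BASES,
    CodonAlignment,
    PairwiseDnDs,
    _jc_correct,
    classify_regime,
    codon_pair_differences,
    codon_sites,
    gene_average,
    genetic_code,
    pairwise_dnds,
    strip_stops_and_validate,
)

CODE = genetic_code(1)
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")

# a fixed, diverse 16-codon probe set (all four first bases represented)
PROBE_CODONS = [
    "TTT", "TTA", "TCT", "TAT", "TGT", "CTT", "CCC", "CGA",
    "ATT", "ATG", "ACA", "AAA", "GTT", "GCC", "GAA", "GGG",
]


def oracle_translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> tuple[float, float]:
    syn = 0.0
    aa = oracle_translate(codon)
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if oracle_translate(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    diffs = [i for i in range(3) if a[i] != b[i]]

    def paths(cur, remaining):
        if not remaining:
            yield []
            return
        for i in remaining:
            nxt = cur[:i] + b[i] + cur[i + 1:]
            if oracle_translate(nxt) == "*" and len(remaining) > 1:
                continue
            for tail in paths(nxt, [j for j in remaining if j != i]):
                yield [(cur, nxt)] + tail

    all_paths = list(paths(a, diffs))
    if not all_paths:  # every route blocked by stops: use unrestricted routes
        def paths_any(cur, remaining):
            if not remaining:
                yield []
                return
            for i in remaining:
                nxt = cur[:i] + b[i] + cur[i + 1:]
                for tail in paths_any(nxt, [j for j in remaining if j != i]):
                    yield [(cur, nxt)] + tail

        all_paths = list(paths_any(a, diffs))
    syn = non = 0.0
    for path in all_paths:
        for frm, to in path:
            if oracle_translate(frm) == oracle_translate(to):
                syn += 1
            else:
                non += 1
    n = len(all_paths)
    return syn / n, non / n


class TestSiteCounts:
    def test_ttt_splits_one_third_synonymous(self):
        s, n = codon_sites("TTT", CODE)
        assert s == pytest.approx(1 / 3, abs=1e-12)
        assert n == pytest.approx(8 / 3, abs=1e-12)

    @pytest.mark.parametrize("codon", SENSE)
    def test_site_conservation_and_oracle_agreement(self, codon):
        s, n = codon_sites(codon, CODE)
        es, en = oracle_sites(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        assert s == pytest.approx(es, abs=1e-9)


class TestDifferenceCounts:
    def test_identical_codons_no_differences(self):
        assert codon_pair_differences("ATG", "ATG", CODE) == (0.0, 0.0)

    def test_synonymous_single_change(self):
        sd, nd = codon_pair_differences("TTT", "TTC", CODE)
        assert (sd, nd) == (1.0, 0.0)

    def test_nonsynonymous_single_change(self):
        sd, nd = codon_pair_differences("AAA", "AGA", CODE)
        assert (sd, nd) == (0.0, 1.0)

    def test_all_single_mutants_of_probe_codons_match_oracle(self):
        for codon in PROBE_CODONS:
            for pos in range(3):
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    mutant = codon[:pos] + b + codon[pos + 1:]
                    got = codon_pair_differences(codon, mutant, CODE)
                    want = oracle_differences(codon, mutant)
                    assert got == pytest.approx(want, abs=1e-9), (codon, mutant)

    def test_multi_difference_pairs_match_pathway_oracle(self):
        for a in PROBE_CODONS:
            for b in PROBE_CODONS:
                if a == b:
                    continue
                got = codon_pair_differences(a, b, CODE)
                want = oracle_differences(a, b)
                assert got == pytest.approx(want, abs=1e-9), (a, b)


class TestStripStops:
    def test_terminal_stop_removed(self):
        assert strip_stops_and_validate([("x", "ATGAAATAA")]) == [("x", "ATGAAA")]

    def test_internal_stop_is_a_frame_error(self):
        with pytest.raises(ValueError, match="internal stop"):
            strip_stops_and_validate([("y", "ATGTAAAAA")])

    def test_unequal_codon_counts_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            strip_stops_and_validate([("a", "ATGAAA"), ("b", "ATGAAAGGG")])

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            strip_stops_and_validate([("a", "ATGA")])


class TestPairwise:
    def test_identical_sequences_zero_rates(self):
        aln = CodonAlignment([("a", "ATGAAATTT"), ("b", "ATGAAATTT")])
        (p,) = pairwise_dnds(aln)
        assert p.Nd == p.Sd == 0 and p.dN == p.dS == 0

    def test_pure_synonymous_pair(self):
        # Leu codons pad the synonymous sites so the correction is defined
        aln = CodonAlignment([("a", "CTGCTGCTGTTT"), ("b", "CTGCTGCTGTTC")])
        (p,) = pairwise_dnds(aln)
        assert p.Nd == 0 and p.Sd == 1 and p.dN == 0 and p.dS > 0

    def test_single_codon_synonymous_pair_counts(self):
        # at one codon the proportion saturates the correction, but the
        # raw counts are still exact
        aln = CodonAlignment([("a", "TTT"), ("b", "TTC")])
        (p,) = pairwise_dnds(aln)
        assert p.Nd == 0 and p.Sd == 1 and p.dN == 0
        assert p.saturated

    def test_pure_nonsynonymous_pair_omega_infinite(self):
        aln = CodonAlignment([("a", "ATGAAA"), ("b", "ATGAGA")])
        (p,) = pairwise_dnds(aln)
        assert p.Sd == 0 and p.Nd == 1 and p.dS == 0 and p.dN > 0
        assert math.isinf(p.omega)

    def test_site_conservation_per_pair(self):
        rng = random.Random(5)
        seqs = [
            ("s%d" % k, "".join(rng.choice(SENSE) for _ in range(40)))
            for k in range(4)
        ]
        for p in pairwise_dnds(CodonAlignment(seqs)):
            assert p.N + p.S == pytest.approx(3 * p.n_codons, abs=1e-9)

    def test_symmetry_under_sequence_exchange(self):
        # moderate divergence: mutate a fifth of the codons of s1
        rng = random.Random(6)
        codons = [rng.choice(SENSE) for _ in range(50)]
        mutated = list(codons)
        for i in rng.sample(range(50), 10):
            mutated[i] = rng.choice(SENSE)
        s1, s2 = "".join(codons), "".join(mutated)
        (p_ab,) = pairwise_dnds(CodonAlignment([("a", s1), ("b", s2)]))
        (p_ba,) = pairwise_dnds(CodonAlignment([("b", s2), ("a", s1)]))
        for attr in ("N", "S", "Nd", "Sd", "dN", "dS"):
            assert getattr(p_ab, attr) == pytest.approx(
                getattr(p_ba, attr), nan_ok=True
            )

    def test_gapped_codons_skipped_in_both(self):
        aln = CodonAlignment([("a", "ATG---AAA"), ("b", "ATGTTTAGA")])
        (p,) = pairwise_dnds(aln)
        assert p.n_codons == 2

    def test_correction_matches_raw_proportion_at_low_divergence(self):
        # one synonymous change over many codons: d ~= p to first order
        seq_a = "ATG" + "TTT" * 600
        seq_b = "ATG" + "TTT" * 599 + "TTC"
        (p,) = pairwise_dnds(CodonAlignment([("a", seq_a), ("b", seq_b)]))
        assert p.dS == pytest.approx(p.pS, rel=5e-3)

    def test_saturated_proportion_flagged(self):
        assert math.isnan(_jc_correct(0.8, 100.0)[0])


class TestGeneAverage:
    def pair(self, dN, dS):
        return PairwiseDnDs(
            id_a="a", id_b="b", N=100, S=50, Nd=dN * 100, Sd=dS * 50,
            pN=dN, pS=dS, dN=dN, dS=dS, se_dN=0.01, se_dS=0.02,
            n_codons=50,
        )

    def test_ratio_of_means_not_mean_of_ratios(self):
        g = gene_average([self.pair(0.1, 0.5), self.pair(0.3, 1.5)])
        assert g.mean_dN == pytest.approx(0.2)
        assert g.mean_dS == pytest.approx(1.0)
        assert g.omega == pytest.approx(0.2)
        # asymmetric pairs separate the two conventions:
        # ratio of means = 0.2/0.75; mean of ratios would be 0.35
        g2 = gene_average([self.pair(0.1, 1.0), self.pair(0.3, 0.5)])
        assert g2.omega == pytest.approx(0.2 / 0.75)
        assert g2.omega != pytest.approx(0.35)

    def test_single_pair_average_is_that_pair(self):
        g = gene_average([self.pair(0.12, 0.8)])
        assert (g.mean_dN, g.mean_dS) == (0.12, 0.8)
        assert g.n_pairs == 1

    def test_ses_averaged_but_ignored_by_omega(self):
        g = gene_average([self.pair(0.1, 0.5), self.pair(0.3, 1.5)])
        assert g.mean_se_dN == pytest.approx(0.01)
        assert g.mean_se_dS == pytest.approx(0.02)

    def test_saturated_pairs_excluded_with_warning(self):
        sat = self.pair(0.1, 0.5)
        sat.dS = math.nan
        g = gene_average([sat, self.pair(0.2, 1.0)])
        assert g.n_excluded_saturated == 1
        assert g.mean_dN == pytest.approx(0.2)

    def test_all_saturated_regime_undefined(self):
        sat = self.pair(0.1, 0.5)
        sat.dS = math.nan
        g = gene_average([sat])
        assert g.regime == "undefined"

    def test_four_sequence_fixture_matches_per_pair_oracle(self):
        rng = random.Random(11)
        seqs = [("s%d" % k, "".join(rng.choice(SENSE) for _ in range(60)))
                for k in range(4)]
        pairs = pairwise_dnds(CodonAlignment(seqs))
        assert len(pairs) == 6
        g = gene_average(pairs, gene_label="fixture")
        usable = [p for p in pairs if not p.saturated]
        assert g.mean_dN == pytest.approx(
            sum(p.dN for p in usable) / len(usable)
        )
        assert g.omega == pytest.approx(
            (sum(p.dN for p in usable) / len(usable))
            / (sum(p.dS for p in usable) / len(usable))
        )


class TestRegime:
    @pytest.mark.parametrize(
        "omega, expected",
        [(0.23, "purifying"), (1.0, "neutral"), (1.4, "positive"),
         (0.96, "neutral"), (math.inf, "undefined"), (math.nan, "undefined")],
    )
    def test_classification(self, omega, expected):
        assert classify_regime(omega) == expected
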