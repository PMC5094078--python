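"""Grammar tests: candidate rules, completeness, TMD subtyping, accessory
families, topology expectations, and an independent brute-force matcher."""

import random

import pytest

from conftest import make_annotation

from immunome.grammar import (
    classify_candidate,
    classify_other_immune,
    detect_tmd_subtype,
    extract_domain_subsequence,
    presence_flags,
    validate_topology,
)
from immunome.pipeline import classify_catalog
from immunome.records import FamilyCall, TmdSegment

TIR = ("TIR", "PF01582", "CL0173")
TIR2 = ("TIR_2", "PF13676", "CL0173")
LRR = ("LRR_8", "PF13855", "CL0022")
IG = ("I-set", "PF07679", "CL0011")
RHD = ("RHD_DNA_bind", "PF00554", "CL0159")
ANK = ("Ank", "PF00023", "CL0465")
NACHT = ("NACHT", "PF05729", "CL0023")
CARD = ("CARD", "PF00619", "CL0041")
DD = ("Death", "PF00531", "CL0041")
PKINASE = ("Pkinase", "PF00069", "CL0016")
HOM = (("sp|P12345|TLR4_MOUSE", "Mus musculus"),)


class TestClassifyCandidate:
    def test_tir_plus_lrrs_is_complete_tlr(self, rules):
        ann = make_annotation(domains=[TIR] + [LRR] * 12, tmds=[(600, 622)],
                              homology=HOM)
        call = classify_candidate(ann, rules)
        assert call.family == "TLR" and call.completeness == "complete"
        assert call.n_repeat_domains["LRR"] == 12
        assert call.membrane_bound

    def test_empty_domain_list_is_unclassified(self, rules):
        assert classify_candidate(make_annotation(), rules) is None

    def test_nacht_lrr_card_is_nlr_with_card_subtype(self, rules):
        ann = make_annotation(domains=[CARD, NACHT] + [LRR] * 5, homology=HOM)
        call = classify_candidate(ann, rules)
        assert call.family == "NLR"
        assert call.death_fold_type == "CARD"

    def test_rhd_without_ankyrin_is_partial_nfkb_with_note(self, rules):
        ann = make_annotation(domains=[RHD], homology=HOM)
        call = classify_candidate(ann, rules)
        assert call.family == "NFKB"
        assert call.completeness == "partial"
        assert "RHD-only" in call.notes

    def test_rhd_with_ankyrins_is_complete_nfkb(self, rules):
        ann = make_annotation(domains=[RHD] + [ANK] * 4, homology=HOM)
        call = classify_candidate(ann, rules)
        assert call.family == "NFKB" and call.completeness == "complete"

    def test_tir_dd_kinase_routes_to_novelty_not_myd88(self, rules):
        ann = make_annotation(domains=[PKINASE, DD, TIR2])
        assert classify_candidate(ann, rules) is None

    def test_tir_dd_without_kinase_is_myd88(self, rules):
        ann = make_annotation(domains=[DD, TIR], homology=HOM)
        call = classify_candidate(ann, rules)
        assert call.family == "MyD88"

    def test_tir2_substitutes_for_tir_and_is_recorded(self, rules):
        ann = make_annotation(domains=[TIR2] + [LRR] * 3, homology=HOM)
        call = classify_candidate(ann, rules)
        assert call.family == "TLR"
        assert any(h.family_accession == "PF13676" for h in call.evidence)

    def test_nlr_precedes_tlr_when_both_match(self, rules):
        ann = make_annotation(domains=[NACHT, TIR] + [LRR] * 4, homology=HOM)
        assert classify_candidate(ann, rules).family == "NLR"


class TestCompleteness:
    def test_full_orf_with_homology_and_canonical_domains(self, rules):
        ann = make_annotation(domains=[DD, TIR], homology=HOM)
        assert classify_candidate(ann, rules).completeness == "complete"

    def test_missing_stop_codon_demotes_to_partial(self, rules):
        ann = make_annotation(domains=[DD, TIR], homology=HOM, has_stop=False)
        assert classify_candidate(ann, rules).completeness == "partial"

    def test_no_homology_hit_demotes_to_partial(self, rules):
        ann = make_annotation(domains=[DD, TIR])
        assert classify_candidate(ann, rules).completeness == "partial"

    def test_nucleotide_level_hit_does_not_count(self, rules):
        ann = make_annotation(domains=[DD, TIR], homology=HOM)
        for h in ann.homology:
            object.__setattr__(h, "query_level", "nucleotide")
        assert classify_candidate(ann, rules).completeness == "partial"


class TestTmdSubtype:
    def call(self):
        return FamilyCall("tx1", "NLR", "partial")

    def test_nterm_clustered_helices_flagged(self):
        tmds = [TmdSegment("tx1", s, s + 20) for s in (40, 80, 120, 160)]
        call = detect_tmd_subtype(self.call(), tmds, 1000, 0.30)
        assert call.membrane_bound and call.tmd_n_terminal_clustered
        assert call.n_tmd == 4

    def test_no_tmds_not_membrane_bound(self):
        call = detect_tmd_subtype(self.call(), [], 1000)
        assert not call.membrane_bound and not call.tmd_n_terminal_clustered

    def test_cterminal_helix_not_clustered(self):
        # midpoint at 80% of length
        call = detect_tmd_subtype(self.call(), [TmdSegment("tx1", 790, 810)], 1000)
        assert call.membrane_bound and not call.tmd_n_terminal_clustered


COLLAGEN = ("Collagen", "PF01391", "CL0422")
FIB = ("Fibrinogen_C", "PF00147", "CL0422")
SRCR = ("SRCR", "PF00530", "CL0639")
WAP = ("WAP", "PF00095", "CL0617")


class TestAccessoryFamilies:
    def test_cnifl_records_ig_count_and_membrane(self, rules):
        ann = make_annotation(domains=[COLLAGEN, IG, IG, IG, FIB],
                              tmds=[(100, 122)], homology=HOM)
        (call,) = classify_other_immune(ann, rules=rules)
        assert call.family == "CniFL"
        assert call.n_repeat_domains["Ig"] == 3
        assert call.membrane_bound and not call.has_wap

    def test_cnifl_wap_variant_flagged(self, rules):
        ann = make_annotation(domains=[COLLAGEN, IG, FIB, WAP], homology=HOM)
        (call,) = classify_other_immune(ann, rules=rules)
        assert call.has_wap

    def test_srcr_single_domain_call(self, rules):
        ann = make_annotation(domains=[SRCR], homology=HOM)
        (call,) = classify_other_immune(ann, rules=rules)
        assert call.family == "SRCR"

    def test_cnifl_requires_ig(self, rules):
        ann = make_annotation(domains=[COLLAGEN, FIB], homology=HOM)
        assert classify_other_immune(ann, rules=rules) == []

    def test_masp_needs_all_slots_and_reference_homology(self, rules):
        slots = [("CUB", "PF00431", "CL0164"), ("EGF_CA", "PF07645", "CL0001"),
                 ("CUB", "PF00431", "CL0164"), ("Sushi", "PF00084", "CL0500"),
                 ("Sushi", "PF00084", "CL0500"), ("Trypsin", "PF00089", "CL0124")]
        ref = (("NVE_MASP1", "Nematostella vectensis"),)
        full = make_annotation(domains=slots, homology=ref)
        assert [c.family for c in
                classify_other_immune(full, {"NVE_MASP1"}, rules)] == ["MASP"]
        # same domains, unrelated homology -> no call
        other = make_annotation(domains=slots, homology=HOM)
        assert classify_other_immune(other, {"NVE_MASP1"}, rules) == []
        # one Sushi missing -> no call at the all-six default
        partial = make_annotation(domains=slots[:-2] + slots[-1:], homology=ref)
        assert classify_other_immune(partial, {"NVE_MASP1"}, rules) == []


class TestPresenceFlags:
    def test_c3_hit_marks_present(self, rules):
        ann = make_annotation(homology=(("sp|P01024|Complement_C3", "Homo sapiens"),))
        flags = presence_flags([ann], rules)
        assert flags["C3"] and not flags["C6"]

    def test_empty_catalog_all_absent(self, rules):
        assert set(presence_flags([], rules).values()) == {False}


class TestTopologyValidation:
    def test_tlr_without_tmd_warns(self):
        calls = [FamilyCall("tx1", "TLR", "complete", n_tmd=0)]
        assert len(validate_topology(calls)) == 1

    def test_myd88_without_tmd_is_fine(self):
        assert validate_topology([FamilyCall("tx1", "MyD88", "complete")]) == []

    def test_nfkb_with_tmd_warns(self):
        calls = [FamilyCall("tx1", "NFKB", "complete", n_tmd=1,
                            membrane_bound=True)]
        assert len(validate_topology(calls)) == 1


class TestDomainSubsequence:
    def test_nacht_envelope_clipped(self):
        ann = make_annotation(domains=[("NACHT", "PF05729", "CL0023", 120, 310)])
        (sub,) = extract_domain_subsequence(ann, "PF05729")
        assert len(sub.sequence) == 191
        assert sub.sequence == ann.orf.peptide[119:310]

    def test_absent_accession_gives_empty_list(self):
        assert extract_domain_subsequence(make_annotation(), "PF05729") == []

    def test_duplicate_domains_in_coordinate_order(self):
        ann = make_annotation(domains=[("NACHT", "PF05729", "CL0023", 400, 580),
                                       ("NACHT", "PF05729", "CL0023", 120, 310)])
        subs = extract_domain_subsequence(ann, "NACHT")
        assert [(s.aa_start, s.aa_end) for s in subs] == [(120, 310), (400, 580)]


# --- properties -------------------------------------------------------------

def brute_force_family(labels: set) -> str | None:
    """Independent matcher: test every rule against the label multiset."""
    tir = bool(labels & {"TIR", "TIR_2"})
    if tir and labels & {"Pkinase", "Pkinase_Tyr", "Ras", "Roc", "COR",
                         "Miro", "SH3", "SAM", "BTK", "CBM"}:
        return None
    if "NACHT" in labels:
        return "NLR"
    if tir and "LRR" in labels:
        return "TLR"
    if tir and "Ig" in labels:
        return "IL1R_like"
    if tir and "DD" in labels:
        return "MyD88"
    if "RHD" in labels:
        return "NFKB"
    return None


VOCAB = [TIR, TIR2, LRR, IG, RHD, ANK, NACHT, CARD, DD, PKINASE,
         ("Ras", "PF00071", "CL0023"), ("SH3_1", "PF00018", "CL0010")]


def test_matches_brute_force_matcher_on_random_small_catalogs(rules):
    rng = random.Random(1)
    for _ in range(200):
        picks = [VOCAB[rng.randrange(len(VOCAB))]
                 for _ in range(rng.randint(0, 6))]
        ann = make_annotation(domains=picks, homology=HOM)
        call = classify_candidate(ann, rules)
        expected = brute_force_family(
            {lab for _, lab in rules.label_hits(ann.domains) if lab}
        )
        assert (call.family if call else None) == expected


def test_evidence_contains_all_required_domains(classified_fixture):
    """Grammar soundness: every call's evidence satisfies its rule."""
    _, _, result = classified_fixture
    from immunome.rules import load_rules

    rules = load_rules()
    for call in result.family_calls:
        rule = next((r for r in rules.families if r.family == call.family), None)
        if rule is None:
            continue
        ev_labels = {lab for _, lab in rules.label_hits(call.evidence) if lab}
        assert rule.matches(ev_labels), (call.transcript_id, call.family)


def test_removing_stop_codons_never_increases_complete_count(rules):
    anns = [
        make_annotation(tx=f"t{i}", domains=[DD, TIR], homology=HOM)
        for i in range(5)
    ]
    before = sum(
        classify_candidate(a, rules).completeness == "complete" for a in anns
    )
    for a in anns:
        a.orf.has_stop_codon = False
    after = sum(
        classify_candidate(a, rules).completeness == "complete" for a in anns
    )
    assert after <= before and after == 0


def test_classification_invariant_under_catalog_permutation(classified_fixture,
                                                            known_catalog):
    catalog, truth, result = classified_fixture
    shuffled = list(catalog)
    random.Random(3).shuffle(shuffled)
    res2 = classify_catalog(shuffled, known=known_catalog,
                            masp_reference_ids=set(truth.masp_reference_ids))
    assert [
        (c.transcript_id, c.family, c.completeness) for c in result.family_calls
    ] == [(c.transcript_id, c.family, c.completeness) for c in res2.family_calls]
    assert [(c.transcript_id, c.pattern) for c in result.novelty_calls] == [
        (c.transcript_id, c.pattern) for c in res2.novelty_calls
    ]
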