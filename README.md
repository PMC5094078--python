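# immunome

Profiling the innate-immune gene repertoire of sea anemones (Actiniaria)
from annotated transcriptome assemblies.

Anthozoan cnidarians carry a recognisable core of the eumetazoan innate
immune toolkit — Toll-like receptors, NLRs, the MyD88 adaptor, NF-κB — next
to lineage-specific inventions such as membrane-bound NLRs and novel
TIR-domain proteins. Surveying that repertoire across species means applying
the same domain-architecture rules, the same completeness criteria and the
same counting conventions to every assembly. This package makes those rules
explicit, data-driven and testable.

It is aimed at comparative immunologists and transcriptome annotators who
already have standard annotation artifacts in hand (TransDecoder ORFs, Pfam
domain hits, BLAST homology tables, TMHMM topology calls) and want
reproducible family calls, count tables and selection statistics out of
them. The package never runs the annotation tools itself.

## What it computes

**Architecture grammar.** Conserved candidate families are called from
domain content alone:

| family | rule |
|---|---|
| TLR | TIR (PF01582, or TIR_2 PF13676) + ≥1 LRR (clan CL0022) |
| MyD88 | TIR (or TIR_2) + death domain |
| IL-1R-like | TIR (or TIR_2) + ≥1 Ig (clan CL0011) |
| NF-κB | RHD (PF00554) + ≥1 ankyrin repeat (PF00023); RHD alone stays partial |
| NLR | NACHT + ≥1 LRR, optional death-fold (CARD/PYD/DD/DED) N-terminal domain |

A call is **complete** only when the ORF has start and stop codons, the
peptide has at least one protein-level homology hit, and the canonical
domains are all present. NLRs are additionally subtyped as membrane-bound
when they carry transmembrane helices clustered at the N-terminus (3–5
helices within the first 30 % of the peptide is the canonical pattern).
Accessory families (CniFL = Collagen + Ig + Fibrinogen, MASP, SRCR, C-type
lectin) and homology-only complement components (C3, Factor B, C6, Factor I)
are handled by the same rule file.

**Novelty detection.** TIR/TIR_2-bearing transcripts with no informative
homology (no hits, or hits only to *Nematostella vectensis* predictions) are
screened against a local catalog of known TIR architectures and matched to
recurrent novel patterns: NG1 (LRR + GTPase module + TIR_2), NG2 (1–2 TIR_2
upstream of a BTK zinc-finger), NG3 (overlapping kinase + death domain +
TIR) and TIR-only (including the TIR-like DUF1863). Routing is exclusive —
a TIR + DD + kinase transcript is NG3, never MyD88.

**Count tables.** Per species × family, genes (isoform groups) are counted
both conservatively (≥1 complete isoform) and non-conservatively (any
call), mirroring the twin conventions of comparative immunome tables.

**Selection statistics.** Pairwise dN/dS on codon alignments via
Nei–Gojobori site counting with pathway averaging and the correction
d = −¾·ln(1 − 4p/3), or a transition/transversion-corrected variant
(`yn00` mode) with kappa estimated from four-fold degenerate sites. Per
gene, dN and dS (and their SEs) are averaged over all pairs and
ω = mean(dN)/mean(dS) is reported as the ratio of means; ω < 1 reads as
purifying selection.

**Synthetic fixtures.** A deterministic generator plants all of the above
(families, isoforms, partial ORFs, decoys, membrane NLRs, complement
homology, codon pairs with a controlled ω) with a full truth table, so the
whole pipeline is testable at desk scale with no downloads.

## Worked example

```
$ immunome simulate --seed 42 --out fixture/
wrote fixture with 56 transcripts to fixture

$ immunome ingest --pep fixture/pep.fa --cds fixture/cds.fa \
    --domains fixture/domains.tsv --tmhmm fixture/tmhmm.txt \
    --blast swissprot=fixture/blast_swissprot.tsv \
    --blast trembl=fixture/blast_trembl.tsv \
    --species A_synthetica_1 --out catalog/
wrote 56 annotations to catalog/ (0 warning(s))

$ immunome classify --catalog catalog/ --masp-reference NVE_MASP1 --out calls/
41 family calls, 11 novelty calls
```

`calls/novelty_calls.tsv` then contains rows such as

```
DN28_c0_g1_i1  NG1  no_hits          novel  LRR-Miro-Ras-COR-TIR_2  COR downstream of GTPase module
DN30_c0_g1_i1  NG2  nvectensis_only  novel  TIR_2-TIR_2-BTK
```

— each novel transcript with its matched pattern, why it entered the screen
(no hits at all, or *N. vectensis*-only hits), its verdict against the
known-architecture catalog, and the ordered domain signature.
`immunome report --catalog catalog/ ... --out tables/` aggregates the calls
into the species × family matrix (`TLR_complete 3, TLR_total 3, ...`).

For selection, on a simulated codon pair diverged under ω = 0.2:

```
$ immunome dnds --aln gene.fasta --method yn00 --out dnds/
gene: dN=0.0425 (+/-0.0083) dS=0.2866 (+/-0.0389) dN/dS=0.1482 [purifying]
```

dN and dS are the corrected per-site rates with delta-method standard
errors; `dN/dS` is the ratio of the (per-gene averaged) means, and the
regime label applies the ω < 1 purifying-selection reading.

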