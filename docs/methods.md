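# Methods

## Scope and data model

The pipeline consumes the outputs of standard annotation tools rather than
running them: predicted ORFs (peptide FASTA with TransDecoder-style
completeness tags, optional CDS), Pfam-style domain hits (7-column TSV or
HMMER domtblout, hmmscan orientation), BLAST tabular homology (12 columns,
optional 13th species column) and TMHMM-short transmembrane calls. All
amino-acid coordinates are 1-based inclusive envelope coordinates. Records
merge into one `TranscriptAnnotation` per ORF; transcripts group into genes
by stripping a Trinity-style `_i<n>` isoform suffix (configurable regex;
ungrouped ids count as their own gene).

Domain hits are retained at E ≤ 1e−5 by default. No Pfam-specific
significance threshold is standard across annotation pipelines, so the
homology-search threshold is reused; it is a parameter of every reader.

## Architecture grammar

Family rules live in a versioned YAML file (`immunome/data/rules.yaml`),
not in code. A hit normalises to a grammar label by the first matching
predicate — family accession, then clan accession, then domain name — so
rules citing a clan (LRR = CL0022, Ig = CL0011) match any member family,
while rules citing a family (TIR = PF01582) are exact. A shipped
family→clan map backfills clans for formats (domtblout) that lack them.

Candidate rules and their canonical (completeness-required) domain sets:

* NLR — NACHT required; NACHT + ≥1 LRR canonical. NACHT with only a
  death-fold domain is still a (partial) NLR candidate. The death-fold
  subtype (CARD > PYD > DD > DED, fixed order on ties) is recorded.
* TLR — TIR/TIR_2 + ≥1 LRR. The TIR accession actually seen is kept in
  the evidence; TIR and TIR_2 are interchangeable in every candidate rule.
* IL-1R-like — TIR/TIR_2 + ≥1 Ig.
* MyD88 — TIR/TIR_2 + death domain. The death-domain label accepts
  PF00531 or, as a fallback, any clan-CL0041 hit not already labelled
  CARD/PYD/DED.
* NF-κB — RHD + ≥1 ankyrin repeat canonical; a bare RHD yields a partial
  call annotated "RHD-only" and can never be complete.

Precedence on multi-rule matches is NLR > TLR > IL-1R-like > MyD88 >
NF-κB (most specific co-domain first); ties are logged. Before any
candidate rule is tried, a TIR-bearing transcript carrying
novelty-indicative co-domains (Pkinase/Pkinase_Tyr, Ras/Roc/COR/Miro, SH3,
SAM, BTK, CBM) is routed to the novelty detector — this is what keeps
NG3 (TIR + DD + kinase) out of the MyD88 bin, and the routing is exclusive
in both directions.

A call is complete iff the ORF has start and stop codons, the peptide has
≥1 peptide-level homology hit, and the canonical domain set is present.
Topology is annotated per call: `membrane_bound` when ≥1 helix;
`tmd_n_terminal_clustered` when *all* helix midpoints fall within the first
30 % of the peptide (configurable fraction — the biological pattern is only
qualitative, so the window is a package choice). The membrane-NLR tally
deliberately includes partial NLRs. Expected topologies (TLR and
IL-1R-like membrane-anchored; MyD88 and NF-κB cytosolic; a TMD is not
required for an IL-1R-like call) are enforced only as warnings.

Accessory families: CniFL = Collagen + ≥1 Ig + Fibrinogen, recording Ig
count, WAP presence and membrane anchoring; MASP = six domain slots
(CUB ×2, EGF-like calcium-binding, Sushi ×2, Peptidase S1) — all six by
default, relaxable via `min_slots` — plus homology to a configured
reference MASP; SRCR (PF00530) and C-type lectin (PF00059) are
single-domain calls. Complement components (C3, Factor B, C6, Factor I)
have no domain rule; they are presence/absence flags driven by
case-insensitive regexes over homology subject names.

`extract_domain_subsequence` clips peptides to domain envelopes (e.g. the
NACHT domain ahead of phylogenetic alignment) and writes FASTA; tree
inference itself is out of scope.

## Novelty detection

Candidates are TIR/TIR_2-bearing transcripts whose homology status is
`no_hits` or `nvectensis_only` (every hit's subject species is
*Nematostella vectensis*). DUF1863, documented as a TIR-like domain
appearing in place of TIR in TIR-only architectures, is treated as
TIR-like for candidacy and for the TIR-only class.

Signatures are ordered N→C label tuples after overlap collapsing: hits
overlapping by >50 % of the shorter envelope *and* sharing a clan merge to
the better E-value (the kinase-model doublet Pkinase/Pkinase_Tyr is the
motivating case). Pattern predicates are pure functions of the signature:

* NG1 — LRR + ≥1 of {Miro, Ras, Roc} + TIR_2; a COR domain is recorded as
  supporting evidence but not required, and its reported ~300-aa spacing
  downstream of the GTPase module is not enforced (no tolerance is
  defensible).
* NG2 — one or two TIR_2 domains, all upstream of a BTK zinc-finger motif
  (matched by name; the motif has no dedicated Pfam family in the rule
  file's vocabulary).
* NG3 — (Pkinase or Pkinase_Tyr) + DD + (TIR or TIR_2); SH3/Roc/COR are
  recorded when present.
* TIR-only — signature ⊆ {TIR, TIR_2, DUF1863}.
* anything else TIR-bearing — `unmatched_novel`.

Signatures are also screened against a local known-architecture catalog
(TSV asset; a synthetic compilation of widely reported TIR architectures
standing in for a live domain-architecture database). Matching is
order-sensitive by default because published architectures are ordered;
a flag allows order-insensitive matching. An empty catalog makes
everything novel, with a warning.

## Count tables

Per species × family: `n_complete_genes` (gene groups with ≥1 complete
call — the conservative convention), `n_total_genes` (≥1 call of any
completeness — the non-conservative convention), `n_isoforms` and
`n_partial_genes`. Candidate families report both conventions; accessory
families only the non-conservative count; complement families only +/−
flags. Novel patterns are tallied per gene group. Merging species
zero-fills missing families, keeps input row order and rejects duplicate
labels.

## dN/dS

`strip_stops_and_validate` trims terminal stop codons, rejects internal
stops (frame errors) and unequal codon counts. Alignment is an input; the
package does not align.

The NG86 estimator: per codon, each position contributes one site split by
the fraction of its three single-base changes that are synonymous; changes
to stop codons count as nonsynonymous rather than being excluded, so
N + S = 3 × (compared codons) exactly. Differences between codons are
averaged uniformly over all minimal substitution pathways that avoid stop
codons (all pathways, if every route is blocked — a vanishing case).
Codons with gaps or ambiguity in either sequence are skipped pairwise.
Proportions p = Nd/N, Sd/S are corrected by d = −¾·ln(1 − 4p/3) with
delta-method standard errors se = sqrt(p(1−p)/n)/(1 − 4p/3); p ≥ ¾ is
flagged saturated (NaN).

The `yn00` mode is a transition/transversion-corrected variant in the
spirit of the Yang–Nielsen (2000) approximate method: kappa is estimated
per pair by Kimura-2P from third positions of codons whose first two
positions are conserved and four-fold degenerate in both sequences
(falling back to 1 below 10 usable sites or on log-domain failure), then
used to weight mutational opportunities in the site counts. This removes
the dominant bias of equal-rate counting under transition bias; it is not
a reimplementation of the full codon-frequency-weighted estimator.

Per gene, dN, dS and their SEs are arithmetically averaged over all
pairwise comparisons (saturated pairs excluded with a warning) and
ω = mean(dN)/mean(dS) — the ratio of means, not the mean of ratios, and
the SEs play no part in it. dS = 0 with dN > 0 gives ω = +∞ and regime
"undefined"; dN = dS = 0 gives NaN. The regime classifier uses a ±0.05
neutral band around ω = 1 by default.

## Synthetic data

Peptides are concatenations of per-domain placeholder blocks (fixed
per-label lengths, random linkers); the block coordinates drive the domain
table directly — no similarity search is emulated, because the pipeline
consumes annotations. Defaults plant 3 genes for each of the 9
domain-ruled families, 1–3 isoforms per gene (P = 0.6/0.3/0.1), 30 %
partial ORFs (uniformly 5′-partial, 3′-partial or internal), two decoys
each of RHD-only, TIR-only, NG1, NG2 and NG3, one membrane NLR (3–5
N-terminal helices, C-terminus padded so all helix midpoints sit within the
first quarter of the peptide — the planted geometry must satisfy the
clustering definition it emulates), and homology-only complement
transcripts for C3 and Factor B (present) with C6 and Factor I absent,
matching the pattern reported across actiniarian species. Annotated
transcripts get synthetic Swiss-Prot-style mouse subjects; novel-decoy
transcripts get no hits or *N. vectensis*-only subjects, exercising the
novelty screen. CDS are uniform-random reverse translations of the
peptides. Every emitted byte is a deterministic function of
(config, seed).

What the generator does **not** emulate: real HMM score distributions,
envelope-boundary noise, chimeric/misassembled contigs, allelic variants,
and genuinely ambiguous architectures. Passing recovery tests therefore
demonstrates the correctness of the rule logic and plumbing, not
robustness to annotation noise on real assemblies.

The codon-pair simulator draws a uniform sense-codon ancestor and applies
a Poissonised number of single-nucleotide events (expected `t` = 0.3 per
codon by default — sub-saturation divergence typical of within-family
paralog comparisons) with relative rates kappa (default 2.0, a typical
transition/transversion bias) for transitions and ω for nonsynonymous
changes; stop-creating changes are forbidden. True synonymous and
nonsynonymous event counts are recorded.

## Numerical and design notes

* Problem sizes in the shipped tests and acceptance script (27 + 10
  planted genes per fixture, 20 random count configurations, 10
  membrane-NLR layouts, 100 routing fixtures, 500-codon pairs × 50
  replicates) are chosen so the full run completes in seconds while
  keeping each property statistically meaningful.
* ω recovery is evaluated with the kappa-aware (`yn00`) estimator, the
  appropriate choice when the generating process has transition bias;
  plain NG86 under-estimates ω by ~10–20 % in that regime, which is the
  expected behaviour of equal-rate counting, not an error.
* Classification iterates transcripts in id order, so results are
  invariant under catalog permutation; ties between rules are resolved by
  fixed rule-file order and logged.
* Known limitations: the MyD88 death-domain clan fallback can absorb
  unannotated death-fold variants; the BTK/COR/DUF1863 labels are
  name-matched and depend on the annotator's naming; MASP calling requires
  a user-supplied reference id set; the known-architecture catalog is a
  small synthetic stand-in and should be replaced with a curated export
  for real analyses.
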