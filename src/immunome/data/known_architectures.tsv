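# Local reference catalog of TIR/TIR_2 domain architectures already described
# outside Actiniaria (stand-in for a live Pfam architecture lookup; synthetic
# compilation of widely reported metazoan/bacterial TIR architectures).
# signature: ordered N->C domain labels joined by '-'.
signature	provenance
TIR-LRR	vertebrate TLR-like (ectodomain-less fragments)
LRR-TIR	canonical TLR fragment order
LRR-LRR-TIR	canonical TLR
Ig-Ig-TIR	vertebrate IL-1R family
Ig-Ig-Ig-TIR	vertebrate IL-1R family
DD-TIR	metazoan MyD88
TIR	single-TIR adaptors (SARM-like fragments)
SAM-SAM-TIR	metazoan SARM1
Ig-TIR	IL-1R-like fragment
TIR_2	bacterial single-TIR_2 proteins
TIR_2-TIR_2	bacterial tandem TIR_2
NACHT-LRR	canonical metazoan NLR
CARD-NACHT-LRR	metazoan NLRC-type
PYD-NACHT-LRR	metazoan NLRP-type
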