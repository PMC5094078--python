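family_accession	clan_accession
PF01582	CL0173
PF13676	CL0173
PF13855	CL0022
PF12799	CL0022
PF00560	CL0022
PF13516	CL0022
PF07679	CL0011
PF00047	CL0011
PF13927	CL0011
PF00554	CL0159
PF00023	CL0465
PF12796	CL0465
PF05729	CL0023
PF00619	CL0041
PF02758	CL0041
PF00531	CL0041
PF01335	CL0041
PF00147	CL0422
PF00530	CL0639
PF00059	CL0056
PF00069	CL0016
PF07714	CL0016
PF00071	CL0023
PF08477	CL0023
PF00431	CL0164
PF07645	CL0001
PF00084	CL0500
PF00089	CL0124
PF00018	CL0010
PF00536	CL0003
PF00095	CL0617
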