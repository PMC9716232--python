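variant_name	ccp_module	odds_ratio	amd_allele_freq_pct	gnomad_allele_freq_pct	dbsnp_id
Control	NA	NA	—	0.67	rs1061170(T)
Arg2Thr	Signal peptide	14.08	0.021	0.002	rs142266551
Leu3Val	Signal peptide	1.06	0.333	0.024	rs139254423
Arg53Cys	1 (C3b binding)	22.54	0.078	0.002	rs757785149
Arg53His	1 (C3b binding)	13.39	0.036	ND
Ser58Ala	1 (C3b binding)	2.82	0.072	0.025	rs141336681
Asp90Gly	2 (C3b and factor I binding)	Risk (LOD = 1.22)	0	0.0004	rs1239695899
Asp130Asn	2 (C3b and factor I binding)	10.0	0.09	0.014	rs147002633
Arg175Gln	3 (C3b and factor I binding)	1.50	0.34	ND
Arg175Pro	3 (C3b and factor I binding)	Not known	0.026	0.0004	rs139360826
Ile221Val	4 (C3b binding)	11.80	0.024	0.002	rs774239374
Arg303Trp	5	12.25	0.016	0.006	rs142937931
Arg303Gln	5	9.47	0.01	0.002	rs766408580
Gln400Lys	7 (GAG binding)	Not known	0.089	0.012	rs201671665
Tyr402His	7 (GAG binding)	4.6	0.7	0.33	rs1061170(C)
Pro503Ala	8	Risk (NA)	0.103	0.002	rs570523689
Arg567Gly	10	5.11	0.863	0.0004	rs757756991
Gly650Val	11	1.52	0.073	0.023	rs143237092
Ser890Ile	15	1.03	0.386	2.13	rs515299
Thr956Met	16	1.04	0.275	0.129	rs145975787
Gly1194Asp	20 (C3b or C3d and cell surface/GAG binding)	7.41	0.083	0.001	rs761877050
Arg1210Cys	20 (C3b or C3d and cell surface/GAG binding)	31.8	0.53	0.015	rs121913059
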