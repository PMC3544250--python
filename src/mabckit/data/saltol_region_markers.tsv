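name	chromosome	position_bp	position_mb	forward_primer	reverse_primer	motif	n_repeats	ssr_start	ssr_end	role	polymorphic
RM10694	1	10969040	11.0	TTTCCCTGGTTTCAAGCTTACG	AGTACGGTACCTTGATGGTAGAAAGG	AC	18	10969040	10969075	flank	true
AP3206f	1	11200000	11.2	GCAAGAATTAATCCATGTGAAAGA	AGTGCAGGATCTGCCATGA					flank	true
RM3412b	1	11600000	11.6	TGATGGATCTCTGAGGTGTAAAGAGC	TGCACTAATCTTTCTGCCACAGC					foreground	true
RM10748	1	11758005	11.8	CATCGGTGACCACCTTCTCC	CCTGTCATCTATCTCCCTCAAGC	AG	14	11758005	11758032	flank	true
RM493	1	12264091	12.3	GTACGTAAACGCGGAAGGTGACG	CGACGTACGAGATGCCGATCC	AAG	9	12264091	12264117	foreground	true
RM140	1	12284725	12.3	CTTGCACAAGAGATGATGATGAGC	CATGCTGAGAAATAGTACGCTTGG	AG	12	12284725	12284748	flank	true
RM10825	1	13306166	13.3	GGACACAAGTCCATGATCCTATCC	CTTTCCTTTCCATCCTTGTTGC	AAG	10	13306166	13306195	flank	true
RM562	1	14610402	14.6	GGAAAGGAAGAATCAGACACAGAGC	GTACCGTTCCTTTCGTCACTTCC	AAG	13	14610402	14610446	flank	true
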