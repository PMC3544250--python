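name	chromosome	position_bp	position_mb	forward_primer	reverse_primer	motif	n_repeats	ssr_start	ssr_end	role	polymorphic
SBG01_01	1	3250000	3.2							background	True
SBG01_02	1	6500000	6.5							background	True
SBG01_03	1	9750000	9.8							background	True
SBG01_04	1	19000000	19.0							background	True
SBG01_05	1	22250000	22.2							background	True
SBG01_06	1	25500000	25.5							background	True
SBG01_07	1	28750000	28.8							background	True
SBG01_08	1	32000000	32.0							background	True
SBG01_09	1	35250000	35.2							background	True
SBG01_10	1	38500000	38.5							background	True
SBG01_11	1	41750000	41.8							background	True
SBG02_01	2	4000000	4.0							background	True
SBG02_02	2	8000000	8.0							background	True
SBG02_03	2	12000000	12.0							background	True
SBG02_04	2	16000000	16.0							background	True
SBG02_05	2	20000000	20.0							background	True
SBG02_06	2	24000000	24.0							background	True
SBG02_07	2	28000000	28.0							background	True
SBG02_08	2	32000000	32.0							background	True
SBG03_01	3	3700000	3.7							background	True
SBG03_02	3	7400000	7.4							background	True
SBG03_03	3	11100000	11.1							background	True
SBG03_04	3	14800000	14.8							background	True
SBG03_05	3	18500000	18.5							background	True
SBG03_06	3	22200000	22.2							background	True
SBG03_07	3	25900000	25.9							background	True
SBG03_08	3	29600000	29.6							background	True
SBG03_09	3	33300000	33.3							background	True
SBG04_01	4	4000000	4.0							background	True
SBG04_02	4	8000000	8.0							background	True
SBG04_03	4	12000000	12.0							background	True
SBG04_04	4	16000000	16.0							background	True
SBG04_05	4	20000000	20.0							background	True
SBG04_06	4	24000000	24.0							background	True
SBG04_07	4	28000000	28.0							background	True
SBG04_08	4	32000000	32.0							background	True
SBG05_01	5	3750000	3.8							background	True
SBG05_02	5	7500000	7.5							background	True
SBG05_03	5	11250000	11.2							background	True
SBG05_04	5	15000000	15.0							background	True
SBG05_05	5	18750000	18.8							background	True
SBG05_06	5	22500000	22.5							background	True
SBG05_07	5	26250000	26.2							background	True
SBG06_01	6	4000000	4.0							background	True
SBG06_02	6	8000000	8.0							background	True
SBG06_03	6	12000000	12.0							background	True
SBG06_04	6	16000000	16.0							background	True
SBG06_05	6	20000000	20.0							background	True
SBG06_06	6	24000000	24.0							background	True
SBG06_07	6	28000000	28.0							background	True
SBG07_01	7	3750000	3.8							background	True
SBG07_02	7	7500000	7.5							background	True
SBG07_03	7	11250000	11.2							background	True
SBG07_04	7	15000000	15.0							background	True
SBG07_05	7	18750000	18.8							background	True
SBG07_06	7	22500000	22.5							background	True
SBG07_07	7	26250000	26.2							background	True
SBG08_01	8	3625000	3.6							background	True
SBG08_02	8	7250000	7.2							background	True
SBG08_03	8	10875000	10.9							background	True
SBG08_04	8	14500000	14.5							background	True
SBG08_05	8	18125000	18.1							background	True
SBG08_06	8	21750000	21.8							background	True
SBG08_07	8	25375000	25.4							background	True
SBG09_01	9	3833333	3.8							background	True
SBG09_02	9	7666667	7.7							background	True
SBG09_03	9	11500000	11.5							background	True
SBG09_04	9	15333333	15.3							background	True
SBG09_05	9	19166667	19.2							background	True
SBG10_01	10	3428571	3.4							background	True
SBG10_02	10	6857143	6.9							background	True
SBG10_03	10	10285714	10.3							background	True
SBG10_04	10	13714286	13.7							background	True
SBG10_05	10	17142857	17.1							background	True
SBG10_06	10	20571429	20.6							background	True
SBG11_01	11	3625000	3.6							background	True
SBG11_02	11	7250000	7.2							background	True
SBG11_03	11	10875000	10.9							background	True
SBG11_04	11	14500000	14.5							background	True
SBG11_05	11	18125000	18.1							background	True
SBG11_06	11	21750000	21.8							background	True
SBG11_07	11	25375000	25.4							background	True
SBG12_01	12	3500000	3.5							background	True
SBG12_02	12	7000000	7.0							background	True
SBG12_03	12	10500000	10.5							background	True
SBG12_04	12	14000000	14.0							background	True
SBG12_05	12	17500000	17.5							background	True
SBG12_06	12	21000000	21.0							background	True
SBG12_07	12	24500000	24.5							background	True
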