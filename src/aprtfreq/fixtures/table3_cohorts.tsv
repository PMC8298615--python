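database	population	alt_count	allele_number	printed_percent	printed_homozygote_one_in	printed_carrier_one_in	flag
gnomAD	African	9	24940	0.0360	7679057	1386
gnomAD	Ashkenazi Jewish	1	10350	0.0097
gnomAD	East Asian	9	19946	0.0451	4911641	1109
gnomAD	European (Finnish)	1	24920	0.0080
gnomAD	European (Non-Finnish)	63	128828	0.0489	4181571	1023
gnomAD	Latino	11	35430	0.0508	3712044	964	count_frequency_mismatch
gnomAD	South Asian	5	30614	0.0163	37488680	3062
UK Biobank	All	77	1000000	0.077	1686625	650	allele_number_suspect
100,000 Genomes Project	All	11	127474	0.0086	134294386	5795
deCODE	Iceland	1304	107928	1.2082	6840	42	homozygote_cell_prerounded
deCODE	Denmark	12	17662	0.0678	2166293	736
deCODE	Sweden	3	6306	0.0476	4418404	1052
deCODE	Norway	3	5840	0.0514	3789511	974
deCODE	Ireland	7	2730	0.18315	298116	274	cells_from_founder_variant_only
HGVD	Japan	3	2326	0.1289	601142	388
KOVA	Korea	1	1898	0.052687	3602404	950
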