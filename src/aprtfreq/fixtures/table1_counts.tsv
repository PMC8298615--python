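variant_id	database	population	alt_count	allele_number
c.407T>C	HGVD	Japan	3	2326
c.407T>C	KOVA	Korea	1	1898
c.407T>C	gnomAD	African	0	16760
c.407T>C	gnomAD	Ashkenazi Jewish	0	9956
c.407T>C	gnomAD	East Asian	1	18360
c.407T>C	gnomAD	European (Finnish)	0	20398
c.407T>C	gnomAD	European (Non-Finnish)	0	112090
c.407T>C	gnomAD	Latino	0	34518
c.407T>C	gnomAD	Other	0	6066
c.407T>C	gnomAD	South Asian	0	30590
c.194A>T	deCODE	Iceland	1299	107928
c.194A>T	deCODE	Sweden	1	6306
c.194A>T	deCODE	Denmark	1	17662
c.194A>T	100,000 Genomes Project	UK	1	127474
c.194A>T	gnomAD	African	0	24072
c.194A>T	gnomAD	Ashkenazi Jewish	0	10156
c.194A>T	gnomAD	East Asian	0	19736
c.194A>T	gnomAD	European (Finnish)	0	24188
c.194A>T	gnomAD	European (Non-Finnish)	1	124598
c.194A>T	gnomAD	Estonian	1	4768
c.194A>T	gnomAD	Latino	0	35102
c.194A>T	gnomAD	Other	0	7032
c.194A>T	gnomAD	South Asian	0	30262
c.400+2dup	UK Biobank	UK	22	1000000
c.400+2dup	100,000 Genomes Project	UK	4	127474
c.400+2dup	deCODE	Ireland	5	2730
c.400+2dup	deCODE	Denmark	4	17662
c.400+2dup	gnomAD	African	1	24940
c.400+2dup	gnomAD	Ashkenazi Jewish	0	10350
c.400+2dup	gnomAD	East Asian	0	19942
c.400+2dup	gnomAD	European (Finnish)	0	24890
c.400+2dup	gnomAD	European (Non-Finnish)	27	128838
c.400+2dup	gnomAD	South European	5	11592
c.400+2dup	gnomAD	Other non-Finnish European	10	32948
c.400+2dup	gnomAD	North-West European	11	50708
c.400+2dup	gnomAD	Swedish	1	26100
c.400+2dup	gnomAD	Latino	1	35430
c.400+2dup	gnomAD	Other	0	7280
c.400+2dup	gnomAD	South Asian	1	30614
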