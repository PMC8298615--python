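variant_id	database	population	alt_count	allele_number
c.194A>T	deCODE	Iceland	1299	107928
c.1A>C	deCODE	Iceland	4	107928
c.329T>C	deCODE	Iceland	1	107928
c.329T>C	deCODE	Denmark	5	17662
c.400+2dup	deCODE	Denmark	4	17662
c.1A>C	deCODE	Denmark	2	17662
c.194A>T	deCODE	Denmark	1	17662
c.1A>C	deCODE	Sweden	1	6306
c.194A>T	deCODE	Sweden	1	6306
c.521_523del	deCODE	Sweden	1	6306
c.400+2dup	deCODE	Ireland	5	2730
c.541T>C	deCODE	Ireland	2	2730
c.250G>A	deCODE	Norway	2	5840
c.521_523del	deCODE	Norway	1	5840
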