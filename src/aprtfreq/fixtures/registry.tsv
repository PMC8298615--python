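variant_id	cdna	protein	region	build38_pos	printed_label
c.194A>T	c.194A>T	p.(Asp65Val)	Exon 3	16:88810550	Missense
c.1A>C	c.1A>C	p.(Met1?)	Exon 1	16:88811899	Nonsense
c.329T>C	c.329T>C	p.(Leu110Pro)	Exon 4	16:88810141	Missense
c.400+2dup	c.400+2dup	p.(Ala108Glufs*3)	Intron 4	16:88810067	Indel
c.521_523del	c.521_523del	p.(Phe174del)	Exon 5	16:88809717	Deletion
c.541T>C	c.541T>C	p.(*181Argext*?)	Exon 5	16:88809700	Stop lost
c.250G>A	c.250G>A	p.(Val84Met)	Exon 3	16:88810494	Missense
c.407T>C	c.407T>C	p.(Met136Thr)	Exon 5		Missense
c.294G>A	c.294G>A	p.(Trp98*)	Exon 3		Nonsense
c.81-3C>G	c.81-3C>G		Intron 1		Splice
c.58C>T	c.58C>T	p.(Pro20Ser)	Exon 1		Missense
c.23dup	c.23dup	p.(Val9Glyfs*2)	Exon 1		Frameshift
c.522_524del	c.522_524del	p.(Ser175del)	Exon 5		Deletion
c.264G>T	c.264G>T	p.(Lys88Asn)	Exon 3		Missense
c.227C>T	c.227C>T	p.(Ala76Val)	Exon 3		Missense
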