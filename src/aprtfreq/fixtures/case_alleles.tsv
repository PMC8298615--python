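variant_id	case_allele_count
c.407T>C	223
c.194A>T	80
c.400+2dup	65
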