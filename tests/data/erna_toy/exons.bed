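chr1	52500	52600	exon_2	0	+
chr1	112500	112600	exon_5	0	+
chr1	172500	172600	exon_8	0	+
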