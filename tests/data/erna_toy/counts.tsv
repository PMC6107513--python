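locus	shCTR_rep1	shCTR_rep2	shKD_rep1	shKD_rep2
chr1:9900-11100	30	30	10	10
chr1:29900-31100	30	30	75	75
chr1:69900-71100	24	36	45	45
chr1:89900-91100	60	60	30	30
chr1:129900-131100	30	30	60	60
chr1:149900-151100	9	9	9	9
chr1:189900-191100	6	6	3	3
chr1:209900-211100	0	0	0	0
chr1:229900-231100	36	36	36	36
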