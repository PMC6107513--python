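chr1	11100	11500	k4me1_0	0	.
chr1	31100	31500	k4me1_1	0	.
chr1	51100	51500	k4me1_2	0	.
chr1	71100	71500	k4me1_3	0	.
chr1	91100	91500	k4me1_4	0	.
chr1	111100	111500	k4me1_5	0	.
chr1	131100	131500	k4me1_6	0	.
chr1	151100	151500	k4me1_7	0	.
chr1	171100	171500	k4me1_8	0	.
chr1	191100	191500	k4me1_9	0	.
chr1	211100	211500	k4me1_10	0	.
chr1	231100	231500	k4me1_11	0	.
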