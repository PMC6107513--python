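chr1	10000	11000	k27ac_0	0	.
chr1	30000	31000	k27ac_1	0	.
chr1	50000	51000	k27ac_2	0	.
chr1	70000	71000	k27ac_3	0	.
chr1	90000	91000	k27ac_4	0	.
chr1	110000	111000	k27ac_5	0	.
chr1	130000	131000	k27ac_6	0	.
chr1	150000	151000	k27ac_7	0	.
chr1	170000	171000	k27ac_8	0	.
chr1	190000	191000	k27ac_9	0	.
chr1	210000	211000	k27ac_10	0	.
chr1	230000	231000	k27ac_11	0	.
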