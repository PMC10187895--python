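feature_type	name	position_bp	blocks	efficiency
length	.	4640000	.	.
oriC	oriC	3920000	.	.
dif	dif	1590000	.	.
ter	TerA	1340000	ccw	1.0
ter	TerB	1680000	cw	1.0
ter	TerG	2400000	cw	0.5
locus	ydcM	1510000	.	.
locus	lepA	2700000	.	.
locus	qseC	3100000	.	.
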