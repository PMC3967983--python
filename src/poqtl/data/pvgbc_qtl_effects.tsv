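# Per-QTL allelic-effect significance calls in the PVGBC population (PVG background),
# transcribed from the published reciprocal-backcross summary table.
# Two QTLs (5a:25 and 13:58) were significant only in the entire population and
# carry cross = POP (no per-cross detection); they count toward population totals.
qtl	sex	chrom	pos_mb	shared	ons_pop	max_pop	wl_pop	ons_pvgxf1	max_pvgxf1	wl_pvgxf1	ons_f1xpvg	max_f1xpvg	wl_f1xpvg	allele	cross	trans
3:161	F	3	161	yes	0.01	0.01	ns	ns	ns	ns	0.003	0.001	0.05	D	F1xPVG	Mat
4a:144	F	4	144	yes	0.04	ns	ns	ns	ns	ns	0.003	0.01	ns	D	F1xPVG	Mat
6:131	F	6	131	yes	ns	0.05	ns	0.05	ns	ns	ns	ns	ns	P	PVGxF1	Pat
7b:50	F	7	50	yes	ns	ns	ns	0.04	0.02	ns	ns	ns	ns	D	PVGxF1	.
10a:23	F	10	23	yes	0.007	0.03	ns	ns	ns	ns	0.003	0.01	ns	D	F1xPVG	Mito?
10b:50	F	10	50	yes	0.005	0.009	0.01	ns	ns	ns	0.04	0.008	0.002	D	ALL	.
10c:82	F	10	82	no	ns	ns	0.02	0.003	0.009	0.04	ns	ns	ns	D	PVGxF1	Pat
1a:25	M	1	25	no	ns	ns	0.03	ns	ns	ns	0.02	0.006	0.002	P	F1xPVG	Mat
4a:144	M	4	144	yes	0.002	0.02	0.02	ns	ns	ns	0.0003	0.001	0.04	D	F1xPVG	Mat
6:131	M	6	131	yes	0.04	ns	ns	0.002	0.006	ns	ns	ns	ns	P	PVGxF1	Pat
10a:23	M	10	23	yes	ns	ns	ns	ns	ns	ns	0.04	ns	ns	D	F1xPVG	Mito?
10b:50	M	10	50	yes	0.005	ns	ns	ns	ns	ns	0.005	0.02	ns	D	ALL	.
10c:82	M	10	82	no	ns	ns	ns	ns	0.05	ns	ns	ns	ns	D	PVGxF1	Pat
18:80	M	18	80	yes	ns	ns	ns	ns	ns	ns	0.004	0.003	0.002	P	F1xPVG	Mat
5a:25	both	5	25	no	ns	ns	ns	ns	ns	ns	ns	ns	ns	D	POP	.
13:58	both	13	58	no	ns	ns	ns	ns	ns	ns	ns	ns	ns	D	POP	.
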