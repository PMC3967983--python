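# Per-QTL allelic-effect significance calls in the DABC population (DA background),
# transcribed from the published reciprocal-backcross summary table.
# p-values are Student's t at the QTL peak; ns = not significant (> 0.05).
# cross: reciprocal cross in which the QTL was identified (ALL = both crosses).
# trans: published transmission call (Mat/Pat/Mito?/.) kept for cross-checking.
qtl	sex	chrom	pos_mb	shared	ons_pop	max_pop	wl_pop	ons_daxf1	max_daxf1	wl_daxf1	ons_f1xda	max_f1xda	wl_f1xda	allele	cross	trans
1b:248	F	1	248	no	ns	ns	ns	ns	ns	ns	ns	ns	0.04	P	ALL	.
4a:144	F	4	144	yes	0.002	0.03	0.01	ns	ns	ns	9e-5	0.001	0.008	D	F1xDA	Mat
4b:185	F	4	185	no	0.001	0.002	0.006	0.02	ns	ns	0.02	ns	0.02	D	ALL	.
5b:157	F	5	157	no	0.02	0.004	0.003	ns	ns	ns	0.001	0.0001	0.0001	P	F1xDA	Mat
6:131	F	6	131	yes	ns	ns	0.02	0.03	ns	0.01	ns	ns	ns	P	DAxF1	Pat
7a:21	F	7	21	no	0.03	0.03	ns	ns	0.04	0.05	ns	ns	ns	P	ALL	.
7b:50	F	7	50	yes	ns	ns	ns	ns	ns	ns	ns	0.03	0.03	D	F1xDA	.
10d:98	F	10	98	no	0.02	0.005	ns	ns	0.02	ns	0.05	ns	ns	D	ALL	.
12:25	F	12	25	no	0.003	0.0004	5e-5	0.01	0.004	0.0006	ns	0.04	0.02	D	ALL	.
14:5	F	14	5	no	0.02	ns	ns	ns	ns	ns	0.0003	0.02	ns	P	F1xDA	Mat
1b:248	M	1	248	no	ns	0.002	8e-5	ns	ns	0.04	ns	0.01	0.007	P	ALL	.
3:161	M	3	161	yes	ns	ns	ns	ns	ns	ns	ns	0.04	0.05	D	F1xDA	Mat
4a:144	M	4	144	yes	ns	ns	ns	ns	ns	ns	ns	ns	0.006	D	F1xDA	Mat
10a:23	M	10	23	yes	0.004	0.006	ns	ns	0.03	ns	0.03	ns	ns	D	ALL	Mito?
10b:50	M	10	50	yes	0.004	0.007	0.01	ns	ns	ns	0.008	ns	ns	D	ALL	.
11:47	M	11	47	no	0.008	0.04	0.004	0.01	0.05	0.007	ns	ns	ns	D	ALL	.
18:80	M	18	80	yes	ns	ns	ns	ns	ns	ns	0.02	ns	ns	P	F1xDA	Mat
19:50	M	19	50	no	0.009	0.01	0.02	ns	ns	ns	ns	ns	ns	D	ALL	.
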