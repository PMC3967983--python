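# Cross-by-QTL interaction p-values (drop-one F of the QTLxCROSS term from the
# full multiple-QTL model) for the ten single-cross candidate QTLs, transcribed
# from the published interaction table.  population: sub-population giving the
# most significant interaction (Pm = PVGBC males, Pf = PVGBC females,
# Dm = DABC males, Df = DABC females).  NA = no evidence for a QTL, not testable.
qtl	population	inc	max	dur	ons	wl
1a:25	Pm	0.036	0.033	NA	NA	0.020
3:161	Pf	0.031	0.028	NA	0.101	NA
4a:144	Df	0.031	0.036	NA	0.048	0.260
5b:157	Df	NA	0.025	0.029	0.093	0.047
6:131	Pm	0.019	0.034	0.006	0.018	NA
7b:50	Df	NA	NA	NA	0.686	0.027
10a:23	Pf	0.487	0.486	0.176	0.181	NA
10c:82	Pf	NA	NA	0.031	0.009	NA
14:5	Df	0.035	NA	NA	0.020	NA
18:80	Pm	0.037	0.039	0.021	NA	0.040
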