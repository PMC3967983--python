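# Origin-by-QTL interaction p-values in the (DAxPVG) G10 advanced intercross
# (794 rats; origin = G9 parental/family origin), transcribed from the published
# G10 interaction table.  NA = no evidence for a QTL in G10, not testable.
qtl	inc	max	dur	ons	wl
1a:25	0.006	0.05	0.1	0.04	0.01
3:161	0.03	0.004	0.005	0.03	0.03
4a:144	0.0003	0.0009	0.002	0.00001	0.03
5b:157	0.003	0.005	0.003	0.0007	0.005
6:131	NA	NA	NA	NA	NA
7b:50	0.2	NA	NA	0.04	NA
10a:23	0.3	0.5	0.5	0.5	NA
10c:82	0.005	0.006	0.005	0.0006	0.04
14:5	0.0006	0.003	0.02	0.02	0.01
18:80	NA	NA	NA	NA	NA
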