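# Group summary statistics (mean, SD, n) for the DABC reciprocal-cross
# comparison, transcribed from the published comparison table.  Weight is grams
# at immunization; WL is percent weight loss.
population	sex	cross	n	phenotype	mean	sd
DABC	F	DAxF1	105	weight	105.7	12.7
DABC	F	DAxF1	105	INC	0.61	0.5
DABC	F	DAxF1	105	MAX	1.98	1.65
DABC	F	DAxF1	105	DUR	13.17	11.88
DABC	F	DAxF1	105	ONS	21.25	11.97
DABC	F	DAxF1	105	WL	6.64	12.33
DABC	F	F1xDA	108	weight	108.9	11.8
DABC	F	F1xDA	108	INC	0.67	0.49
DABC	F	F1xDA	108	MAX	1.91	1.52
DABC	F	F1xDA	108	DUR	12.39	10.96
DABC	F	F1xDA	108	ONS	20.72	12.21
DABC	F	F1xDA	108	WL	4.53	10.94
DABC	M	DAxF1	104	weight	167.3	24.3
DABC	M	DAxF1	104	INC	0.60	0.51
DABC	M	DAxF1	104	MAX	1.68	1.53
DABC	M	DAxF1	104	DUR	11.7	11.56
DABC	M	DAxF1	104	ONS	22.42	12.95
DABC	M	DAxF1	104	WL	5.05	11.56
DABC	M	F1xDA	104	weight	180.4	19.8
DABC	M	F1xDA	104	INC	0.77	0.47
DABC	M	F1xDA	104	MAX	2.21	1.43
DABC	M	F1xDA	104	DUR	16.18	11.71
DABC	M	F1xDA	104	ONS	19.04	13.13
DABC	M	F1xDA	104	WL	10.01	13.49
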