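context	coord	ADAGAGD	TIGACAI	ADAGAGI
CpG	104060054	0.53	0.87	0.58
CpG	104060087	0.34	0.65	0.36
CpG	104060156	0.37	0.70	0.41
CpG	104060164	0.42	0.74	0.46
CpG	104060226	0.54	0.86	0.55
CpG-SNP	104060367	0.88	0.01	0.84
CpH	104060373	0.03	0.01	0.06
CpH/CpG-SNP	104060378	0.04	0.98	0.12
CpH	104060380	0.06	0.00	0.03
CpH	104060381	0.08	0.00	0.04
CpG-SNP	104060384	0.89	0.00	0.89
CpH-SNP	104060386	0.04	0.01	0.03
CpH	104060389	0.05	0.02	0.06
CpH	104060390	0.05	0.01	0.05
CpG-SNP	104060391	0.91	0.04	0.92
CpG-SNP	104060421	0.06	0.97	0.85
CpG	104060427	0.92	0.99	0.93
CpG	104060464	0.95	0.99	0.94
CpG	104060678	0.65	0.84	0.76
CpG	104060845	0.87	0.94	0.87
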