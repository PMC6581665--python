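# Published morphometric summaries (mean +/- SD over N = 20 haploid
# metaphases) for the two main karyotypes of the Lariophagus distinguendus
# species complex: n5 (Sitophilus-associated species, n = 5) and n6
# (Stegobium-associated species, n = 6).  Values exactly as printed.
karyotype_id	label	rl_mean	rl_sd	ci_mean	ci_sd	n_metaphases	class
n5	1	29.48	1.77	47.06	3.16	20	metacentric
n5	4	23.03	1.15	46.13	2.25	20	metacentric
n5	5	19.19	0.75	47.25	1.79	20	metacentric
n5	6	14.98	0.91	43.74	3.83	20	metacentric
n5	7	13.32	0.86	44.49	4.58	20	metacentric
n6	2	16.68	0.89	45.45	4.08	20	metacentric
n6	3	12.86	0.94	0	0	20	acrocentric
n6	4	22.55	1.28	43.27	3.30	20	metacentric
n6	5	19.86	1.05	46.96	2.69	20	metacentric
n6	6	15.35	0.83	45.83	2.64	20	metacentric
n6	7	12.70	0.83	46.10	3.23	20	metacentric
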