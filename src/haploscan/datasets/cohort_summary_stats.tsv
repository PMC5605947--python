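analysis	gene	chrom	bp_start	bp_end	beta_gs	se_gs	p_gs	beta_elsa	se_elsa	p_elsa	beta_ukb	se_ukb	p_ukb	direction	p_meta
genomewide	.	18	64252341	64568113	0.23	0.05	5.21e-7	0.08	0.06	0.17	0.01	0.02	0.54	+++	0.001
genomewide	.	3	165337109	166522847	0.60	0.12	4.09e-7	-0.02	0.15	0.9	0.06	0.06	0.36	+-+	0.003
genomewide	.	20	9288522	9726640	0.55	0.11	2.13e-7	-0.003	0.06	0.96	0.04	0.05	0.38	+-+	0.008
genomewide	.	1	150165849	151140732	0.51	0.10	9.20e-7	0.12	0.14	0.37	0.002	0.06	0.97	+++	0.01
genomewide	.	4	11448182	11547967	0.32	0.06	7.36e-7	0.11	0.07	0.96	0.01	0.03	0.83	+++	0.04
genomewide	.	11	20184958	20297638	-0.56	0.11	4.31e-7	-0.03	0.13	0.84	0.12	0.06	0.04	--+	0.6
genomewide	.	15	94701431	94729657	-0.27	0.05	6.33e-7	-0.10	0.07	0.14	0.02	0.01	0.16	--+	0.85
gene_region	BDNF	11	27337843	27778592	0.34	0.12	0.007	0.27	0.15	0.08	.	.	.	++?	0.001
gene_region	BDNF	11	27444517	27787783	0.31	0.12	0.01	0.24	0.15	0.11	.	.	.	++?	0.003
gene_region	BDNF	11	27337843	27778592	0.22	0.09	0.01	0.10	0.09	0.27	.	.	.	++?	0.009
gene_region	BDNF	11	27662826	27990119	0.25	0.09	0.006	0.07	0.10	0.47	.	.	.	++?	0.01
gene_region	BDNF	11	27020461	27749725	-0.28	0.11	0.01	-0.10	0.10	0.31	.	.	.	--?	0.02
gene_region	DAOA	13	106140780	106393146	0.25	0.11	0.03	0.16	0.14	0.23	0.20	0.06	3.54e-4	+++	1.53e-5
gene_region	DAOA	13	106098389	106240125	0.28	0.11	0.009	0.08	0.11	0.47	0.13	0.05	0.005	+++	2.63e-4
gene_region	DAOA	13	106140780	106240125	0.22	0.10	0.02	0.08	0.10	0.42	0.12	0.04	0.005	+++	4.03e-4
gene_region	DAOA	13	106066286	106154577	-0.22	0.12	0.07	-0.06	0.14	0.67	-0.22	0.07	0.002	---	5.91e-4
gene_region	DAOA	13	106065361	106133365	-0.18	0.11	0.12	-0.04	0.13	0.75	-0.20	0.06	0.001	---	6.50e-4
gene_region	APOE	19	45290685	45422561	0.28	0.11	0.009	0.18	0.13	0.16	0.14	0.07	0.05	+++	7.50e-4
gene_region	APOE	19	45318153	45422561	0.27	0.09	0.003	0.20	0.10	0.05	0.06	0.05	0.28	+++	0.002
gene_region	APOE	19	45389224	45548502	0.14	0.08	0.07	0.11	0.09	0.21	0.08	0.04	0.04	+++	0.004
gene_region	APOE	19	45390685	45422561	0.09	0.13	0.45	-0.15	0.13	0.26	-0.17	0.06	0.004	+--	0.01
gene_region	APOE	19	45351746	45422561	0.39	0.10	1.24e-4	-0.09	0.11	0.4	0.08	0.05	0.14	+-+	0.01
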