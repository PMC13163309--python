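rank	gene	pathway	p_adjust	log2fc	fpkm	relevance	score
1	APP	Alzheimer disease	1.20e-8	+1.396	50.00	1.0	5.862
2	FGFR3	Cancer pathway	4.56e-9	−2.146	3.99	0.5	4.966
3	BRAF	Cancer pathway	4.56e-9	−1.528	3.99	0.5	4.966
4	AKT1	Cancer pathway	1.89e-9	−1.005	1.99	0.5	4.936
5	MTOR	Cancer pathway	1.89e-9	−1.180	1.99	0.5	4.936
6	PSEN1	Alzheimer disease	3.50e-7	+1.009	20.50	1.0	4.756
7	NTRK1	Neurodegeneration	1.23e-8	−1.375	2.15	1.0	4.652
8	MEK1	Cancer pathway	1.23e-8	−0.847	2.15	0.5	4.552
9	VEGFA	Angiogenesis	2.50e-7	−0.663	4.20	0.5	4.115
10	MAPT	Neurodegeneration	4.20e-6	−0.620	15.00	1.0	4.088
11	MAOB	Neurodegeneration	7.89e-7	−1.240	5.07	1.0	4.032
12	AGRN	Neurodegeneration	7.89e-7	−0.620	5.07	1.0	4.032
13	EGFR	Cancer pathway	6.78e-8	−0.797	0.57	0.5	3.880
14	PARP1	DNA repair	6.78e-8	+1.003	0.57	0.5	3.880
15	CDK5	Neurodegeneration	9.00e-7	+1.384	1.20	1.0	3.564
16	BACE1	Alzheimer disease	7.80e-6	−2.117	5.50	1.0	3.564
17	SNCA	Neurodegeneration	2.10e-5	+0.824	8.00	1.0	3.490
18	GSK3β	Alzheimer disease	4.07e-7	−2.043	0.16	1.0	3.459
19	HES4	Neurodegeneration	4.07e-7	−0.889	0.16	1.0	3.459
20	SOD2	Oxidative stress	5.00e-6	−0.877	3.00	0.5	3.350
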