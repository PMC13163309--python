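compound_name	compound_id	formula	mz	rt_min	target	docking_score	dg_bind
Lactol	HMDB0303945	C20H24O6	378.19013	3.939	MAOB	−9.698	−33.86
4′,5,7-Trihydroxy-6-prenylflavanone	HMDB0037247	C20H20O5	358.16398	3.227	MAOB	−8.848	−48.29
3′-Deoxythymidine	HMDB0246094	C10H14N2O4	227.1062	5.839	MAOB	−8.032	−35.119
Cibaric acid	HMDB0038580	C18H28O5	366.22678	4.971	MAOB	−7.905	−54.944
3′-Amino-3′-deoxythimidine	HMDB0060750	C10H15N3O4	242.11701	4.038	MAOB	−7.744	−39.218
2′,3′-Dideoxyuridine	HMDB0245547	C9H12N2O4	213.09057	4.976	MAOB	−7.632	−41.707
Caryatin glucoside	HMDB0037352	C24H26O12	529.13309	4.025	MAOB	−7.566	−30.277
Biocytin	HMDB0003134	C16H28N4O4S	414.21116	4.469	MAOB	−7.476	−59.884
Amino(1H-indol-2-yl)acetic acid	CSID32887546	C10H10N2O2	191.08118	3.17	MAOB	−7.463	−41.74
Thymidine	HMDB0000273	C10H14N2O5	243.10105	5.406	MAOB	−7.326	−31.752
Lactol	HMDB0303945	C20H24O6	378.19013	3.939	BRAF	−7.931	−64.179
6″-O-Acetylglycitin	HMDB0039489	C24H24O11	489.13817	5.524	BRAF	−7.802	−77.906
Aloesol 7-glucoside	HMDB0040565	C19H24O9	438.17503	4.058	BRAF	−7.778	−57.564
4′,5,7-Trihydroxy-6-prenylflavanone	HMDB0037247	C20H20O5	358.16398	3.227	BRAF	−7.454	−53.497
5-Methyldeoxycytidine	HMDB0002224	C10H15N3O4	283.13964	2.036	BRAF	−7.316	−46.352
6-Ketoestriol	HMDB0000530	C18H22O4	344.18475	6.526	BRAF	−7.183	−45.055
Sergliflozin A	HMDB0258246	C20H24O7	418.18493	3.22	BRAF	−7.058	−53.923
Lactucin	HMDB0035814	C15H16O5	318.13286	3.633	BRAF	−6.893	−36.205
2′,3′-Dideoxyadenosine	HMDB0245544	C10H13N5O2	277.14047	6.718	BRAF	−6.769	−51.332
Nicotine glucuronide	HMDB0001272	C16H22N2O6	356.18075	1.84	BRAF	−6.601	−50.498
2″-O-Acetylrutin	HMDB0039929	C29H32O17	691.12656	8.193	BACE1	−6.13	−51.487
Fluocinolone	HMDB0252347	C21H26F2O6	454.20623	2.966	BACE1	−5.883	−54.185
Amino(1H-indol-2-yl)acetic acid	CSID32887546	C10H10N2O2	191.08118	3.17	BACE1	−5.715	−40.305
Quercetin 3-(6″-malonyl-glucoside)	HMDB0037368	C24H22O15	551.10198	4.937	BACE1	−5.694	−72.447
Aloesol 7-glucoside	HMDB0040565	C19H24O9	438.17503	4.058	BACE1	−5.693	−55.974
3′-Deoxythymidine	HMDB0246094	C10H14N2O4	227.1062	5.839	BACE1	−5.623	−37.631
Aflatoxin G2	HMDB0030475	C17H14O7	331.08041	6.708	BACE1	−5.621	−45.966
Sergliflozin A	HMDB0258246	C20H24O7	418.18493	3.22	BACE1	−5.554	−59.878
25-Hydroxyvitamin D3-26,23-lactone	HMDB0060126	C27H40O4	451.28331	11.375	BACE1	−5.381	−50.272
Lactucin	HMDB0035814	C15H16O5	318.13286	3.633	BACE1	−5.277	−45.832
Amino(1H-indol-2-yl)acetic acid	CSID32887546	C10H10N2O2	191.08118	3.17	GSK3β	−7.872	−49.268
2′,3′-Dideoxyadenosine	HMDB0245544	C10H13N5O2	277.14047	6.718	GSK3β	−7.168	−46.263
7-Methylinosine	HMDB0003950	C11H15N4O5	325.139	1.031	GSK3β	−6.693	−51.859
6-Ketoestriol	HMDB0000530	C18H22O4	344.18475	6.526	GSK3β	−6.65	−55.158
Protocatechuic acid 4-glucoside	HMDB0303826	C13H16O9	339.06788	2.983	GSK3β	−6.625	−59.802
Nicotine glucuronide	HMDB0001272	C16H22N2O6	356.18075	1.84	GSK3β	−6.571	−58.084
Aloesol 7-glucoside	HMDB0040565	C19H24O9	438.17503	4.058	GSK3β	−6.565	−68.261
Sergliflozin A	HMDB0258246	C20H24O7	418.18493	3.22	GSK3β	−6.108	−38.478
Lactol	HMDB0303945	C20H24O6	378.19013	3.939	GSK3β	−6.014	−32.732
5-Methyldeoxycytidine	HMDB0002224	C10H15N3O4	283.13964	2.036	GSK3β	−5.923	−41.794
3′-Deoxythymidine	HMDB0246094	C10H14N2O4	227.1062	5.839	PARP1	−7.791	−45.312
Aloesol 7-glucoside	HMDB0040565	C19H24O9	438.17503	4.058	PARP1	−7.701	−72.594
Quercetin 3-(6″-malonyl-glucoside)	HMDB0037368	C24H22O15	551.10198	4.937	PARP1	−7.454	−95.369
7-Methylinosine	HMDB0003950	C11H15N4O5	325.139	1.031	PARP1	−7.255	−69.042
Quercetin 3-O-(6″-acetyl-glucoside)	HMDB0029271	C23H22O13	507.11242	3.718	PARP1	−7.172	−85.366
2″-O-Acetylrutin	HMDB0039929	C29H32O17	691.12656	8.193	PARP1	−7.07	−69.72
Pyroglutamylvaline	HMDB0094651	C10H16N2O4	229.12191	5.782	PARP1	−7.051	−51.081
Zeranol	HMDB0032702	C18H26O5	364.2109	4.259	PARP1	−6.869	−55.965
Kasugamycin	CSID16736502	C14H25N3O9	402.14996	1.915	PARP1	−6.738	−73.803
Nicotine glucuronide	HMDB0001272	C16H22N2O6	356.18075	1.84	PARP1	−6.665	−57.541
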