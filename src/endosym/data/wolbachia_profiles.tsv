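sample_id	class	order	family	genus	gatB	coxA	hcpA	ftsZ	fbpA	st	supergroup	novel_loci	novel_st
Morph0023	Insecta	Hymenoptera	-	-	near 301	303	317	near 32	353	ST-N1	A	coxA,hcpA	1
Morph0076	Arachnida	Araneae	Phrurolithidae	Orthobula	310	7	320	32	471	ST-544	A	gatB,hcpA,fbpA	1
Morph0080	Insecta	Diptera	Phoridae	Dohrniphora	46	288	321	266	472	ST-547	A	hcpA,ftsZ,fbpA	1
Morph0082	Insecta	Hymenoptera	Platygastridae	-	311	304	322	267	473	ST-548	A	gatB,coxA,hcpA,ftsZ,fbpA	1
Morph0095	Insecta	Hymenoptera	Formicidae	Cardiocondyla	3	305	356	258	474	ST-550	A	coxA,hcpA,ftsZ,fbpA	1
Morph0152	Insecta	Hymenoptera	Platygastridae	Dicroscelio	313	241	323	3	17	ST-553	A	gatB,hcpA	1
Morph0171	Insecta	Hymenoptera	Diapriidae	Trichopria	87	111	103	70	120	ST-554	A		1
Morph0182	Insecta	Hymenoptera	Platygastridae	Idris	314	307	324	3	120	ST-555	A	gatB,coxA,hcpA	1
Morph0189	Insecta	Hymenoptera	Bethylidae	Laelius	22	308	24	3	23	ST-556	A	coxA	1
Morph0269	Insecta	Hymenoptera	Platygastridae	Scelio	315	311	328	271	477	ST-562	A	gatB,coxA,hcpA,ftsZ,fbpA	1
Morph0293	Insecta	Hymenoptera	Platygastridae	Telenomus	316	313	330	272	351	ST-564	A	gatB,coxA,hcpA,ftsZ	1
Morph0294	Insecta	Hymenoptera	Platygastridae	-	317	7	344	273	479	ST-565	A	gatB,hcpA,ftsZ,fbpA	1
Morph0324	Insecta	Hymenoptera	Platygastridae	-	322	313	330	272	351	ST-575	A	gatB,coxA,hcpA,ftsZ	1
Morph0330	Arachnida	Araneae	Uloboridae	Uloborus	319	315	1	3	217	ST-567	A	gatB,coxA	1
Morph0352	Insecta	Coleoptera	Corylophidae	-	320	15	348	6	17	ST-569	A	gatB,hcpA	1
Morph0375	Insecta	Coleoptera	Chrysomelidae	Monolepta	321	316	349	154	122	ST-570	A	gatB,coxA,hcpA	1
Morph0376	Insecta	Hymenoptera	Formicidae	Pheidole	3	305	350	258	474	ST-571	A	coxA,hcpA,ftsZ,fbpA	1
Morph0001	Insecta	Orthoptera	Gryllidae	Neonemobius	9	224	30	20	25	ST-541	B		1
Morph0098	Insecta	Hemiptera	Aphididae	Phorodon	9	224	30	20	25	ST-541	B		1
Morph0213	Insecta	Hemiptera	Psyllidae	Heteropsylla	250	66	88	15	417	ST-559	B		1
Morph0220	Insecta	Hemiptera	Delphacidae	-	250	66	88	15	417	ST-559	B		1
Morph0009	Insecta	Hemiptera	Pyrrhocoridae	Dysdercus	309	287	316	265	7	ST-542	B	gatB,hcpA,ftsZ	1
Morph0026	Insecta	Orthoptera	Gryllidae	Loxoblemmus	9	224	318	20	25	ST-543	B	hcpA	1
Morph0111	Insecta	Hemiptera	Delphacidae	Nilaparvata	107	87	29	35	27	ST-163	B		0
Morph0210	Insecta	Coleoptera	Chrysomelidae	Bruchus	39	310	326	270	27	ST-558	B	coxA,hcpA,ftsZ	1
Morph0214	Insecta	Hemiptera	Delphacidae	Muellerianella	9	2	327	36	9	ST-560	B	hcpA	1
Morph0285	Insecta	Diptera	Phoridae	-	39	14	40	36	4	ST-41	B		0
Morph0288	Insecta	Hemiptera	-	-	9	312	329	7	478	ST-563	B	coxA,hcpA,fbpA	1
Morph0329	Insecta	Hemiptera	Cicadellidae	Balclutha	318	314	345	274	480	ST-566	B	gatB,coxA,hcpA,ftsZ,fbpA	1
Morph0343	Insecta	Hymenoptera	Encyrtidae	-	near 217	7	346	275	359	ST-N2	B	hcpA,ftsZ	1
Morph0348	Insecta	Coleoptera	Chrysomelidae	-	16	14	347	23	4	ST-568	B	hcpA	1
Morph0381	Insecta	Hemiptera	Cicadellidae	Agalliopsis	109	87	351	35	27	ST-572	B	hcpA	1
Morph0386	Insecta	Hemiptera	Cicadellidae	-	126	66	352	15	136	ST-573	B	hcpA	1
Morph0396	Insecta	Hemiptera	Lygaeidae	Nysius	16	14	353	73	4	ST-574	B	hcpA	1
Morph0148	Arachnida	Araneae	Gnaphosidae	Zelotes	312	306	319	268	475	ST-552	F	gatB,coxA,hcpA,ftsZ,fbpA	1
Morph0206	Insecta	Hymenoptera	Formicidae	Paratrechina	73	309	325	269	476	ST-557	F	coxA,hcpA,ftsZ,fbpA	1
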