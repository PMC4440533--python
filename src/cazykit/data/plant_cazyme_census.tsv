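species_id	organism	lineage_group	genome_mbp	total_genes	cazyme_genes	pct_cazyme_genes	cazyme_domains	GT	GH	PL	CE	CBM
VolCa	Volvox carteri	green_algae	138	14520	490	3.37	645	283	85	4	65	102
ChlRe	Chlamydomonas reinhardtii	green_algae	121	15143	574	3.79	741	367	85	4	76	87
PhyPa	Physcomitrella patens	bryophyte_lycophyte	480	35938	1236	3.44	1519	664	392	41	250	172
SelMo	Selaginella moellendorffii	bryophyte_lycophyte	212	22285	1224	5.49	1476	637	370	27	281	161
BraDi	Brachypodium distachyon	monocot	272	25532	1418	5.55	1723	764	394	20	334	211
OrySa	Oryza sativa	monocot	420	42109	1724	4.09	2040	891	498	29	389	233
ZeaMa	Zea mays	monocot	2300	30579	1920	6.28	2256	1026	578	22	394	236
SorBi	Sorghum bicolor	monocot	730	34496	1751	5.08	1431	784	474	23	288	171
AquCo	Aquilegia coerulea	eudicot	302	24823	1554	6.26	1464	657	471	32	360	141
MimGu	Mimulus guttatus	eudicot	312	26718	1671	6.25	1992	680	503	43	363	201
VitVi	Vitis vinifera	eudicot	490	30434	1424	4.68	1710	664	525	39	305	177
EucGr	Eucalyptus grandis	eudicot	641	36376	2542	6.99	3334	1233	823	54	534	360
CitCl	Citrus clementina	eudicot	301	24533	1971	8.03	2328	862	572	41	413	205
CitSi	Citrus sinensis	eudicot	319	25376	2439	9.61	2927	1049	735	52	498	267
CarPa	Carica papaya	eudicot	372	27873	1131	4.06	1341	466	380	25	209	124
AraTh	Arabidopsis thaliana	eudicot	119	27400	1505	5.49	1787	697	483	49	341	217
PruPe	Prunus persica	eudicot	227	27852	1591	5.71	1843	654	491	34	337	180
CucSa	Cucumis sativus	eudicot	243	26682	2157	8.08	2157	779	555	36	355	184
GlyMa	Glycine max	eudicot	975	54175	2839	5.24	3429	1412	917	69	645	386
PopTr	Populus trichocarpa	eudicot	422	41335	2252	5.45	2677	1057	713	55	479	373
RicCo	Ricinus communis	eudicot	350	31237	1540	4.93	1864	605	486	36	328	186
ManEs	Manihot esculenta	eudicot	533	30666	1957	6.38	2365	825	616	42	377	239
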