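uniprot	entrez	gene_name	chrom	seq_no	position	distance	element_type	length	copies
D6WZP1	662564	Altered disjunction	9	1	5'	18773	Satellite	734	2.0
D6WZP3	662624	Ras-related protein Rab-26	9	1	3'	7795	Satellite	734	2.0
D6WZL9	661947	Probable serine/threonine-protein kinase	9	2	Inside		Satellite	993	2.8
D6X226	660275	Arrest	9	3	5'	99669	Satellite	716	2.0
D6X238	661741	Numb	9	3	3'	115984	Satellite	716	2.0
	100141832	no match on uniprot	9	4	5'	1520	Satellite	517	1.4
D6X2D0	660440	Short-chain dehydrogenase	9	4	3'	6704	Satellite	517	1.4
D6X1E7	656884	Cytochrome P450 306A1	9	5	5'	404270	Satellite	1058	2.9
D6X2U7	656977	Elongase	9	5	3'	9947	Satellite	1058	2.9
D6X2C4	660195	Dopamine receptor 1	9	6	Inside		Satellite	304	0.8
D6X2U7	656977	Elongase	9	7	5'	7128	Satellite	394	1.1
D6X366	657055	elongation of very long chain fatty acids protein	9	7	3'	50111	Satellite	394	1.1
D6X0D7	657748	Ret oncogene	9	8	5'	56625	Satellite	213	0.6
D6X0E1	657829	Dpr9	9	8	3'	62781	Satellite	213	0.6
D6X2H8	654954	ADAM metalloprotease	9	9	Inside		Transposon	1107
D6X2U7	655561	Elongase	9	10	5'	47902	Transposon	1085
D6X2V3	655640	Putative uncharacterized protein	9	10	3'	67953	Transposon	1085
D6X244	655011	Serine/threonine-protein kinase 32B	9	11	Inside		Transposon	1062
D6X374	100141521	Putative uncharacterized protein	9	12	Inside		Satellite	292	0.8
D6X2C4	660195	Dopamine receptor 1	9	13	Inside		Transposon	900
D6X259	656290	Transport and Golgi organization 13	9	14	5'	9456	Satellite	222	0.6
D6X260	656373	Protein-tyrosine sulfotransferase	9	14	3'	33523	Satellite	222	0.6
D6X075	658603	MICAL-like protein	9	15	5'	39684	Satellite	203	0.6
D6X1P2	658891	tiptop	9	15	3'	142821	Satellite	203	0.6
D6X095	659195	Troponin C	9	16	5'	3922	Transposon	589
D6X0I1	659336	Troponin C	9	16	3'	15143	Transposon	589
D6X1J0	655713	Transporter	9	17	Inside		Satellite	915	2.5
D6WF56	100141877	zinc finger protein 250	3	18	5'	125685	Satellite	1208	3.4
D6WF61	656924	Transcription initiation factor TFIID subunit 7	3	18	3'	64294	Satellite	1208	3.4
D6WGB1	659040	Mahya	3	19	5'	115537	Satellite	687	1.9
D6WGB5	659201	V-type proton ATPase subunit E	3	19	3'	82217	Satellite	687	1.9
D6WII0	100141571	NADH dehydrogenase, putative	3	20	5'	4278	Transposon	635
D6WII2	100142263	Putative uncharacterized protein	3	20	3'	18585	Transposon	635
D6WFT8	657535	WD repeat-containing protein 47	3	21	Inside		Satellite	604	1.7
D6WDY2	656125	Kynurenine aminotransferase	3	22	5'	10696	Transposon	1000
D6WDY4	656298	Annexin IX	3	22	3'	11599	Transposon	1000
D6WFK8	656174	ankyrin 2,3/unc44	3	23	Inside		Transposon	1081
D6WFX1	657874	ral guanine nucleotide exchange factor	3	24	5'	64025	Transposon	888
D6WFX3	658031	galactose-1-phosphate uridylyltransferase	3	24	3'	3958	Transposon	888
D6WDQ4	659233	Putative uncharacterized protein	3	25	5'	15051	Transposon	1016
D6WDQ6	659376	coiled-coil domain containing 96	3	25	3'	9162	Transposon	1016
D6WF68	655042	glucose dehydrogenase	3	26	5'	25896	Transposon	1067
C3XZ92	655348	Mitogen-activated protein kinase kinase kinase kinase 2	3	26	3'	92876	Transposon	1067
D6WE82	658463	Putative uncharacterized protein	3	27	Inside		Transposon	314
D6WHX6	658191	Putative uncharacterized protein	3	28	5'	173881	Transposon	826
D6WI58	658343	Cathepsin L	3	28	3'	82559	Transposon	826
D6WDJ9	656922	Putative uncharacterized protein	3	29	5'	173548	Transposon	1084
D6WDN0	657559	PRMT5	3	29	3'	383809	Transposon	1084
D6WGS3	656976	Putative uncharacterized protein	3	30	5'	37572	Satellite	216	0.6
D6WGT0	100142515	calpain 3	3	30	3'	226707	Satellite	216	0.6
D6WDS8	660532	Muscle-specific protein 300	3	31	5'	378626	Transposon	1060
D6WDT0	654860	Phosphatidylinositol-binding clathrin assembly protein	3	31	3'	7855	Transposon	1060
D6WHF2	664188	Nephrin	3	32	Inside		Transposon	666
D6WI96	100142620	Heat shock protein 70	3	33	Inside		Transposon	1058
D6WG02	654917	N-acetylglucosaminyltransferase vi	3	34	Inside		Transposon	319
D6WYD1	656891	Putative uncharacterized protein	8	35	5'	385712	Satellite	625	1.7
D6WYN3	654942	serine-type protease inhibitor	8	35	3'	58583	Satellite	625	1.7
D6WYA1	657913	Copia protein (Gag-int-pol protein)	8	36	3'	262	Satellite	196	0.5
D6WYC9	656718	Cmp-n-acetylneuraminic acid synthase	8	37	Inside		Transposon	831
D6WV42	656028	CG5080	8	38	Inside		Transposon	582
D6WYA0	100142507	Beaten path	8	39	5'	7165	Transposon	1181
D6WUX6	662235	Putative uncharacterized protein	8	40	Inside		Transposon	440
D6X0E1	654938	defective proboscis extension response	7	41	Inside		Satellite	722	2.0
D6WPX8	662021	Ribosome-releasing factor 2, mitochondrial	7	42	5'	17480	Transposon	905
A2AX72	662058	Gustatory receptor	7	42	3'	1581	Transposon	905
D6WTD1	661895	similar to chitinase 6	7	43	Inside		Satellite	1440	4.0
D6WPE6	100142073	voltage-gated potassium channel	7	44	Inside		Transposon	814
D2A2C6	663849	Putative uncharacterized protein	4	45	5'	9489	Satellite	549	1.5
D2A2D1	663875	Putative uncharacterized protein	4	45	3'	10920	Satellite	549	1.5
D2A2I0	657017	Putative uncharacterized protein	4	46	5'	5820	Satellite	558	1.6
D2A2I1	657098	Ribonucleoside-diphosphate reductase	4	46	3'	7000	Satellite	558	1.6
D1ZZG6	660983	Kinesin-like protein	4	47	Inside		Transposon	508
D2A2P8	100142595	PiggyBac transposable element	4	48	Inside		Transposon	377
D6WB65	655028	E74	2	49	5'	60525	Satellite	770	2.1
D6WB73	654962	organic cation transporter	2	49	3'	2638	Satellite	770	2.1
D6WBG8	659129	pre-mRNA-splicing helicase BRR2	2	50	3'	4811	Satellite	728
D6WB14	658844	monophenolic amine tyramine	2	51	5'	7955	Transposon	567
D6WB15	658769	Cuticular protein 47Ef	2	51	3'	16173	Transposon	567
D6WB29	657778	Endoprotease FURIN	2	52	Inside		Transposon	1045
A8DIV5	657942	Nicotinic acetylcholine receptor subunit alpha11	2	53	5'	13645	Transposon	1021
D6WB29	657778	Endoprotease FURIN	2	53	3'	4875	Transposon	1021
D6X3I9	661787	Transcription initiation factor IIF	10	54	5'	10025	Satellite	870	2.4
D6X3J1	661827	Putative uncharacterized protein	10	54	3'	6607	Satellite	870	2.4
D6X4P3	655389	Neutral alpha-glucosidase ab	10	55	Inside		Satellite	694	1.9
D6X3H5	661246	Neurexin-4	10	56	5'	2234	Satellite	224	0.6
D6X3H7	661308	Succinate semialdehyde dehydrogenase	10	56	3'	14901	Satellite	224	0.6
D6X4V6	655916	Tubby, putative	10	57	Inside		Transposon	763
D6X3J6	662034	Putative uncharacterized protein	10	58	5'	1015	Satellite	564	1.6
D6X3J7	657069	cdc73 domain protein	10	58	3'	27239	Satellite	564	1.6
D2A693	663231	lysine-specific demethylase 4B	6	59	Inside		Satellite	498	1.4
D2A490	659655	Facilitated trehalose transporter Tret1-2 homolog	6	60	Inside		Transposon	689
D2A6I4	659728	Putative uncharacterized protein	6	61	5'	116030	Transposon	764
D2A6I6	659791	Putative uncharacterized protein	6	61	3'	4860	Transposon	764
D2A3V0	657272	Fasciclin-3	6	62	5'	37286	Satellite	281	0.8
D2A3V3	657421	LIM domain kinase 1	6	62	3'	21789	Satellite	281	0.8
D6W8F4	660322	Disco-related	x	63	Inside		Satellite	530	1.5
D6W8D3	659123	PlexA	x	64	5'	1973	Transposon	848
D6WGD2	659272	Aldose-1-epimerase	x	64	3'	6472	Transposon	848
B3MMG1	657652	Neural-cadherin	5	65	Inside		Satellite	273	0.8
D6WNN6	658579	Transient receptor potential-gamma protein	5	66	5'	2547	Transposon	894
A3RE80	658661	Cardioacceleratory peptide receptor	5	66	3'	27105	Transposon	894
A1JUG2	661207	Ultraspiracle	5	67	Inside		Satellite	379	1.1
D6WNB3	656063	Y box protein	5	68	5'	14993	Satellite	455	1.3
D6WNB6	656095	Peptide chain release factor 1	5	68	3'	350365	Satellite	455	1.3
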