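# Transcribed table of segregating variants in genes hit in multiple
# families of the 18-family chronic CSC exome cohort (one row per variant
# per family; the MARF1/KIAA0430 symbol is normalised to MARF1).
family	chrom	pos	rsid	gene	cadd
Family 18	1	94502780	.	ABCA4	21.2
Family 14	1	94508969	rs61751374	ABCA4	20.5
Family 7	3	183905991	rs566108440	ABCF3	26.1
Family 2	3	183908940	rs779795407	ABCF3	35
Family 17	2	241815411	rs140992177	AGXT	23.3
Family 1	2	241810796	rs121908524	AGXT	28.3
Family 7	16	1394822	rs148966323	BAIAP3	25.2
Family 2	16	1394491	rs114280977	BAIAP3	22
Family 2	8	139833569	rs145361557	COL22A1	23.1
Family 12	8	139838971	rs72731614	COL22A1	23.8
Family 18	1	34015872	rs149704396	CSMD2	22.8
Family 14	1	34066488	rs755952714	CSMD2	24.9
Family 1	17	1944871	rs200625064	DPH1	35
Family 2	17	1943099	rs80150196	DPH1	28.4
Family 4	16	15733081	rs150196755	MARF1	28.6
Family 6	16	15729650	rs192438053	MARF1	25.8
Family 1	6	138655606	rs777828045	ARFGEF3	.
Family 2	6	138615130	rs755891726	ARFGEF3	25.3
Family 18	1	109740175	rs940837035	KIAA1324	.
Family 4	1	109734349	rs41279690	KIAA1324	23.3
Family 15	8	28989925	rs145324154	KIF13B	32
Family 11	8	29102864	.	KIF13B	27.8
Family 13	7	91871373	rs34358665	KRIT1	23.6
Family 12	7	91851344	.	KRIT1	24.2
Family 17	18	44089726	rs571539488	LOXHD1	25.6
Family 7	18	44140215	rs759237437	LOXHD1	.
Family 1	14	74971538	rs760036288	LTBP2	32
Family 15	14	74967643	.	LTBP2	27.2
Family 6	17	10426647	rs769778269	MYH2	33
Family 11	17	10424643	rs34161789	MYH2	35
Family 17	10	95137125	rs367618675	MYOF	22
Family 11	10	95079636	rs146626145	MYOF	23.8
Family 3	6	32180684	rs150079294	NOTCH4	24.5
Family 12	6	32163648	rs764118051	NOTCH4	34
Family 9	20	47364384	.	PREX1	23.2
Family 11	20	47282854	rs149524742	PREX1	34
Family 6	20	43945573	rs199904334	RBPJL	25.1
Family 7	20	43942164	.	RBPJL	27.1
Family 7	20	43942170	.	RBPJL	26
Family 3	8	145736819	rs41555416	RECQL4	23.5
Family 13	8	145737142	rs61755067	RECQL4	32
Family 18	3	53126560	rs201230044	RFT1	22
Family 12	3	53126512	rs147740901	RFT1	22.7
Family 17	9	135173569	.	SETX	25.1
Family 12	9	135210039	rs527394446	SETX	28.5
Family 17	16	89965023	rs144328773	TCF25	34
Family 18	16	89972604	rs137901241	TCF25	28.4
Family 17	2	179554624	rs202234172	TTN	26.1
Family 15	2	179628969	rs139504522	TTN	23.6
Family 13	2	179396568	rs201218828	TTN	22.1
Family 11	2	179411137	.	TTN	23.3
Family 14	9	132636952	rs142714756	USP20	32
Family 12	9	132630423	rs148425010	USP20	23.2
Family 10	5	82835589	rs146630369	VCAN	24.2
Family 11	5	82850808	rs768896921	VCAN	28.9
Family 13	14	75245347	.	YLPM1	.
Family 11	14	75265490	.	YLPM1	25.5
Family 17	3	102183076	rs375032047	ZPLD1	48
Family 15	3	102175036	.	ZPLD1	25.7
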