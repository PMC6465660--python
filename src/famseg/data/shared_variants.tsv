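# Transcribed table of rare variants segregating with affection status in
# two families of the 18-family chronic CSC exome cohort. The PTPRB variant
# was carried homozygously by one individual; all others were heterozygous.
families	chrom	pos	rsid	gene	cadd	any_homozygous
Family 7;Family 14	3	4716897	rs114719990	SETD2	23.6	no
Family 13;Family 17	12	108105893	rs11547909	PWP1	24	no
Family 2;Family 16	17	67013913	rs143651746	ABCA9	22.4	no
Family 1;Family 17	3	10413597	rs144118750	ATP2B2	21.8	no
Family 9;Family 10	10	46122195	rs144142701	ZFAND4	26.1	no
Family 2;Family 15	8	142487895	rs147691391	MROH5	24	no
Family 6;Family 17	7	100365542	rs183014219	ZAN	24.7	no
Family 3;Family 13	17	11459147	rs185956842	SHISA6	33	no
Family 7;Family 14	3	53326592	rs35988197	DCP1A	24	no
Family 1;Family 2	12	70949014	rs61758735	PTPRB	27.8	yes
Family 1;Family 10	17	56833502	rs770124556	PPM1E	.	no
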