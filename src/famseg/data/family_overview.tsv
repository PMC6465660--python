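# Transcribed per-family overview of an 18-family chronic central serous
# chorioretinopathy exome cohort: genotyped phenotype tallies and the number
# of rare variants segregating with affection status in each family.
family	n_affected	n_suggestive	n_unaffected	n_segregating
Family 1	2	3	0	75
Family 2	2	0	0	69
Family 3	1	3	2	36
Family 4	1	1	4	14
Family 5	1	2	4	3
Family 6	2	2	1	37
Family 7	1	2	3	17
Family 8	3	0	1	17
Family 9	2	0	2	12
Family 10	2	1	0	58
Family 11	2	1	0	79
Family 12	3	0	0	29
Family 13	2	0	0	71
Family 14	2	0	1	37
Family 15	2	0	0	60
Family 16	2	1	1	21
Family 17	1	1	0	124
Family 18	2	1	2	29
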