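trait	cluster	locus	chrom	range	minus_log10	fae	linkage_qtl	literature
Fe		qFe1	1	841,961~959,278	4.8	0.300
		qFe3	3	4,145,494~4,182,173	3.8	-0.263
		qFe6-1	6	10,055,520~10,274,263	4.2	-0.158
		qFe6-2	6	16,404,065~21,506,253	3.6	0.320	qFe6
		qFe7	7	27,770,508~27,788,464	3.1	0.148	qFe7
		qFe10	10	10,945,859~11,075,230	4.3	0.337
Zn		qZn1	1	6,179,574~6,204,400	3.5	-0.890		id1005056-58 (Norton 2014)
		qZn7	7	22,891,126~26,101,517	3.6	-0.680	qZn7	qZn7 (Huang 2015; Hu 2016); qZN-7 (Lu 2008); id7003641 (Norton 2014)
		qZn9	9	5,174,170~7,387,104	3.4	1.795
		qZn12	12	21,887,797~21,913,241	3.6	-0.398	qZn12
Cd	Clst1a	qCd1-1	1	212,589~434,398	5.2	-0.002	qCd1
		qCd1-2	1	1,603,456~1,905,348	4.5	0.003	qCd1
	Clst1b	qCd1-3	1	8,542,202~18,485,590	6.1	-0.002
	Clst2a	qCd2-1	2	10,199,643~18,518,546	5.8	-0.002
	Clst2b	qCd2-2	2	25,207,241~33,640,277	5.4	-0.002		qCd2b (Zhang 2014)
	Clst3a	qCd3-1	3	1,652,156~2,158,456	4.7	0.002		qCd3 (Zhang 2014)
		qCd3-2	3	3,337,100~3,355,424	4.5	-0.002
	Clst3b	qCd3-3	3	15,185,771~29,212,237	5.2	0.003
		qCd3-4	3	29,214,304~32,538,230	4.7	0.003
		qCd3-5	3	32,638,170~35,155,759	5.9	-0.002		qCd3 (Huang 2015)
	Clst4a	qCd4-1	4	1,112,387~2,047,665	4.4	-0.001
		qCd4-2	4	4,734,877~5,034,318	4.2	0.003
		qCd4-3	4	5,302,854~5,801,556	4.8	-0.002
		qCd4-4	4	6,224,157~6,246,104	4.6	0.002
	Clst4b	qCd4-5	4	16,868,613~16,869,822	4.4	-0.001
		qCd4-6	4	18,424,682~18,529,758	4.8	0.002
	Clst4c	qCd4-7	4	26,418,529~30,460,722	5.2	0.003	qCd4	qCd4-2 (Kashiwagi 2010)
	Clst5a	qCd5-1	5	1,142,167~3,242,916	6.2	-0.002		qCd5 (Zhang 2014)
		qCd5-2	5	4,859,767~4,870,282	4.6	0.002
	Clst5b	qCd5-3	5	8,264,080~8,297,556	4.7	-0.002
	Clst5c	qCd5-4	5	13,797,802~14,052,508	9.9	-0.002
		qCd5-5	5	14,065,017~14,071,607	4.5	0.002
		qCd5-6	5	14,075,029~16,119,884	7.4	-0.002
		qCd5-7	5	16,818,124~19,141,063	6.7	-0.002		qCd5.1 (Huang 2015)
	Clst5d	qCd5-8	5	21,486,695~23,456,509	8.3	-0.002
	Clst6a	qCd6-1	6	4,365,001~4,400,366	4.5	0.004
	Clst6b	qCd6-2	6	10,411,282~11,457,254	4.4	-0.002	qCd6	Segment_on_Chr6 (Ishikawa 2005)
	Clst6c	qCd6-3	6	22,117,058~22,123,339	4.3	0.002		OsLCT1 (Uraguchi 2011)
	Clst6d	qCd6-4	6	27,586,307~27,591,921	4.9	-0.002
		qCd6-5	6	27,919,935~27,938,490	6.3	0.003
		qCd6-6	6	28,441,362~29,887,070	5.3	-0.002		qCd6 (Zhang 2014)
	Clst7a	qCd7-1	7	9,491,735~10,356,836	6.2	0.004		qGCd7/qSCd7 (Ishikawa 2010); qCdp7 (Abe 2013)
	Clst7b	qCd7-2	7	17,677,268~24,927,574	4.7	0.002		qCDCN-7 (Shen 2008)
	Clst8a	qCd8-1	8	098,858~736,546	5.6	-0.002	qCd8	Segment_on_Chr8 (Ishikawa 2005)
	Clst8b	qCd8-2	8	4,494,409~7,760,106	5.4	-0.002
	Clst8c	qCd8-3	8	24,758,957~26,561,629	4.3	-0.002		qCd8 (Zhang 2014)
		qCd8-4	8	27,252,563~27,275,319	7.1	0.003
		qCd8-5	8	27,313,865~27,323,824	5.0	-0.002
		qCd8-6	8	27,425,405~27,460,834	4.9	0.002
		qCd8-7	8	27,501,982~27,582,900	6.9	-0.002
	Clst9a	qCd9-1	9	12,135,431~12,165,192	5.1	-0.002
		qCd9-2	9	12,405,421~17,243,659	7.8	0.004
	Clst10	qCd10-1	10	8,425,690~14,527,032	5.3	-0.002
		qCd10-2	10	16,043,069~18,482,561	5.5	-0.002
	Clst11a	qCd11-1	11	6,233,769~6,354,200	3.2	0.001	qCd11
		qCd11-2	11	8,096,875~8,953,846	7.7	-0.002
		qCd11-3	11	9,162,686~9,204,553	5.3	0.002
		qCd11-4	11	9,396,989~16,643,233	8.6	-0.002
	Clst11b	qCd11-5	11	16,648,036~16,691,008	6.3	0.002
		qCd11-6	11	16,774,292~16,850,863	6.9	-0.002
		qCd11-7	11	16,915,560~20,181,453	5.1	0.002		qCd11 (Kashiwagi 2009)
		qCd11-8	11	23,757,657~23,977,853	4.4	-0.002		qCd11 (Tang 2007)
		qCd11-9	11	25,493,176~27,669,556	4.2	0.002		qCd11 (Tang 2007)
	Clst12a	qCd12-1	12	1,615,274~1,630,986	4.7	-0.002
		qCd12-2	12	2,275,959~2,471,184	5.3	0.004
		qCd12-3	12	2,956,398~8,288,204	4.0	-0.001
	Clst12b	qCd12-4	12	11,270,271~11,777,847	5.9	0.004
		qCd12-5	12	12,194,972~14,140,041	5.1	-0.001
		qCd12-6	12	14,681,128~15,757,691	7.7	0.003
		qCd12-7	12	15,804,848~15,872,325	5.2	-0.002
		qCd12-8	12	16,987,855~17,467,228	4.9	0.002
	Clst12c	qCd12-9	12	24,218,754~25,662,740	4.1	-0.001		qSCd12 (Ishikawa 2010)
Mn		qMn3	3	20,083,700~20,107,682	4.6	1.317
		qMn5	5	15,026,427~15,945,778	4.3	-0.518
		qMn8	8	27,194,754~27,212,235	4.0	0.943
Cu		qCu5	5	3,343,234~3,704,085	5.1	-0.333		qCu5 (Zhang 2014)
		qCu11	11	14,314,371~14,705,331	4.8	0.262
Se		qSe4-1	4	3,566,285~5,597,802	5.6	0.005
		qSe4-2	4	11,568,849~12,645,615	4.2	0.004
		qSe11	11	27,190,782~27,196,075	3.8	0.003
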