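chrom	start	end	ref	alt	gene	vtype	freq
chr1	10412784	10412785	A	G	KIF1B	SNV	3.08
chr1	11190665	11190666	C	T	MTOR	SNV	5.94
chr1	43812575	43812576	T	C	MPL	SNV	6.8
chr1	115256520	.	.	AGGCCAGGCCCGGCACTG	NRAS	Insertion	1.7
chr2	29445271	.	.	CGT	ALK	Insertion	13.72
chr2	29519890	29519891	C	G	ALK	SNV	6.16
chr2	29541234	29541235	C	T	ALK	SNV	6.12
chr2	209108165	209108166	T	C	IDH1	SNV	3.29
chr2	212566836	212566837	C	A	ERBB4	SNV	3.48
chr3	37089070	37089072	ACA	.	MLH1	Deletion	4.38
chr3	41266107	41266108	TC	AA	CTNNB1	Complex	1.82
chr3	47164278	47164279	G	A	SETD2	SNV	7.49
chr3	142224005	142224006	C	A	ATR	SNV	9.17
chr3	142232475	142232476	C	T	ATR	SNV	3.99
chr3	178916946	178916948	GAT	.	PIK3CA	Deletion	7.59
chr3	187447267	187447268	C	T	BCL6	SNV	14.39
chr4	1805528	1805529	T	G	FGFR3	SNV	5.01
chr4	1808929	1808930	G	A	FGFR3	SNV	3.79
chr4	55131212	55131213	A	T	PDGFRA	SNV	17.99
chr4	55152092	55152100	GACATCATG	.	PDGFRA	Deletion	5.61
chr4	68610385	68610386	G	T	GNRHR	SNV	13
chr4	106180857	106180857	C	.	TET2	Deletion	9.39
chr4	106190823	106190824	T	C	TET2	SNV	11.83
chr4	106197175	106197176	G	A	TET2	SNV	11.3
chr5	112175210	.	.	A	APC	Insertion	5.7
chr5	112176361	112176362	C	T	APC	SNV	5.23
chr5	149501448	149501449	G	A	PDGFRB	SNV	4.31
chr5	176517792	176517793	G	A	FGFR4	SNV	6.2
chr5	180057074	180057075	C	T	FLT4	SNV	13.05
chr6	30862397	30862398	G	A	DDR1	SNV	2.17
chr6	117700257	117700258	C	T	ROS1	SNV	5.66
chr6	117714444	117714445	C	T	ROS1	SNV	11.47
chr7	55242467	55242481	AATTAAGAGAAGCAA	TTC	EGFR	Complex	1.2
chr7	55249037	55249038	G	A	EGFR	SNV	2.46
chr7	55249091	55249092	G	C	EGFR	SNV	3.53
chr7	55259514	55259515	T	G	EGFR	SNV	2.16
chr7	116414979	116414980	A	T	MET	SNV	7.79
chr7	140453132	140453136	TTTCA	AT	BRAF	Complex	4.93
chr7	140494237	140494238	G	A	BRAF	SNV	1.47
chr8	92982976	92982977	C	T	RUNX1T1	SNV	21.35
chr8	128753093	128753094	C	A	MYC	SNV	4.48
chr9	5070022	5070027	TCACAA	.	JAK2	Deletion	4.07
chr9	8500789	8500790	C	T	PTPRD	SNV	4.07
chr9	21970965	21970966	C	A	CDKN2A	SNV	9.2
chr9	133760366	133760367	C	A	ABL1	SNV	3.07
chr9	133760951	133760952	A	G	ABL1	SNV	2.16
chr9	139391525	139391526	G	A	NOTCH1	SNV	6.15
chr9	139396741	139396742	T	C	NOTCH1	SNV	10.74
chr9	139409810	139409811	G	T	NOTCH1	SNV	8.93
chr10	43596167	43596168	G	A	RET	SNV	4.26
chr10	63851815	63851816	C	T	ARID5B	SNV	3.65
chr10	89692837	89692842	TCTTGA	.	PTEN	Deletion	2.46
chr10	89717612	89717613	C	A	PTEN	SNV	2.61
chr10	123247618	123247620	GAT	.	FGFR2	Deletion	2.67
chr11	32417910	.	.	ACCGT	WT1	Insertion	5.26
chr11	32439125	32439126	T	G	WT1	SNV	5.93
chr11	64573739	64573740	A	G	MEN1	SNV	4.52
chr11	64575435	.	.	CTGT	MEN1	Insertion	3.63
chr11	108114802	108114803	C	G	ATM	SNV	5.82
chr11	108170483	108170487	TCTCT	.	ATM	Deletion	7.41
chr11	108206581	108206582	A	T	ATM	SNV	2.45
chr12	6704522	6704523	G	A	CHD4	SNV	1.47
chr12	25378590	25378591	C	T	KRAS	SNV	11.68
chr12	25380259	.	.	TGCACTGTACTCCTC	KRAS	Insertion	2.53
chr12	58144504	58144505	G	A	CDK4	SNV	10.31
chr12	115109751	115109752	T	A	TBX3	SNV	9.39
chr13	28599039	28599040	C	T	FLT3	SNV	9.13
chr13	28608104	.	.	AAGCACCTGATCCTAGTACCT	FLT3	Insertion	4.49
chr13	28895609	28895610	C	T	FLT1	SNV	7.31
chr13	28897044	28897045	C	T	FLT1	SNV	7.75
chr13	48934220	48934221	T	C	RB1	SNV	10.32
chr13	48937054	48937055	G	A	RB1	SNV	12.29
chr14	75514889	75514890	G	T	MLH3	SNV	18.81
chr14	105246489	105246490	C	T	AKT1	SNV	2.07
chr15	67358628	67358629	G	A	SMAD3	SNV	16.51
chr15	67457294	67457295	G	T	SMAD3	SNV	17.73
chr16	2126135	2126136	C	T	TSC2	SNV	5.86
chr16	3789660	3789661	C	T	CREBBP	SNV	1.33
chr16	3828109	3828110	C	T	CREBBP	SNV	4.95
chr17	7574001	7574002	C	T	TP53	SNV	2.84
chr17	7577105	.	.	GA	TP53	Insertion	11.64
chr17	29562778	29562779	T	C	NF1	SNV	8.23
chr17	29576056	29576057	G	A	NF1	SNV	3.05
chr17	42327859	42327860	C	T	SLC4A1	SNV	4.22
chr18	48581260	48581261	C	T	SMAD4	SNV	8.08
chr18	60985848	60985849	C	G	BCL2	SNV	6.8
chr19	17943615	17943616	T	A	JAK3	SNV	7.35
chr19	17945516	17945517	T	C	JAK3	SNV	9.5
chr22	22142671	22142672	G	T	MAPK1	SNV	8.87
chr22	23523943	23523944	G	A	BCR	SNV	10.45
chr22	29695597	29695598	G	A	EWSR1	SNV	4.19
chr22	30032780	30032801	GGACTCTGGGGCTCCGAGAAAC	.	NF2	Deletion	1.17
chr22	41564512	41564513	G	A	EP300	SNV	4.87
chrX	53440074	53440075	T	G	SMC1A	SNV	15.15
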