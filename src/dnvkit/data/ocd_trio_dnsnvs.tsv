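proband	chrom	pos_hg19	pos_hg38	ref	alt	hgvs	class	gene	population_af	cadd_phred
TOC065	chr5	5237111	5236998	G	A	NM_139056.4:c.2053G>A(p.Ala685Thr)	missense	ADAMTS16	3.98e-05	29.8
TOC056	chr15	85400980	84857749	C	T	NM_020778.5:c.3011C>T(p.Ala1004Val)	missense	ALPK3	Absent	26.4
TOC007	chr2	202154268	201289545	C	T	NM_001127391.3:c.1054G>A(p.Glu352Lys)	missense	ALS2CR12	Absent	25.1
TOC070	chr17	27934828	29607810	T	C	NM_152345.5:c.183T>C(p.Leu61=)	synonymous	ANKRD13B	Absent	10.54
TOC026	chr11	118772435	118901726	G	A	NM_001378213.1:c.2017C>T(p.Arg673Trp)	missense	BCL9L	5.93e-06	19.18
TOC018	chr9	136898768	134033646	C	T	NM_007371.4:c.2125G>A(p.Glu709Lys)	missense	BRD3	0.00	22.9
TOC049	chr2	29294791	29071925	C	T	NM_001029883.3:c.2337G>A(p.Pro779=)	synonymous	C2orf71	1.27e-05	4.379
TOC047	chr9	132374730	129612451	A	T	NM_199350.4:c.1192T>A(p.Ser398Thr)	missense	C9orf50	8.48e-06	18.46
TOC034	chr19	3613091	3613093	C	T	NM_001080543.2:c.1751G>A(p.Arg584His)	missense	CACTIN	8.53e-07	31
TOC034	chr10	95275285	93515528	C	A	NM_018131.5:c.652C>A(p.Gln218Lys)	missense	CEP55	Absent	24
TOC015	chr6	55989036	56124238	C	T	NM_030820.4:c.1704+1G>A	splice	COL21A1	8.53e-07	33
TOC069	chr7	91763562	92134248	G	A	NM_000786.4:c.117C>T(p.Ala39=)	synonymous	CYP51A1	1.70e-06	14.27
TOC003	chr18	28649000	31069034	C	T	NM_024422.6:c.2368G>A(p.Gly790Arg)	missense	DSC2	0.00	22.6
TOC065	chr1	16641689	16315194	G	A	NM_018994.3:c.225C>T(p.Cys75=)	synonymous	FBXO42	Absent	12.61
TOC017	chr11	49227684	49206132	A	G	NM_004476.3:c.159T>C(p.Thr53=)	synonymous	FOLH1	8.48e-07	3.011
TOC002	chr7	1538340	1498704	C	T	NM_001080453.3:c.1283+3G>A	splice	INTS1	Absent	1.151
TOC056	chr1	15421388	15094892	C	T	NM_201628.3:c.1506C>T(p.Arg502=)	synonymous	KAZN	Absent	10.64
TOC032	chr2	23862064	23639194	G	A	NM_052920.2:c.341G>A(p.Arg114Gln)	missense	KLHL29	1.56e-04	27.8
TOC020	chr15	40678575	40386374	G	A	NM_033286.4:c.317G>A(p.Arg106Gln)	missense	KNSTRN	2.29e-05	24.2
TOC004	chr1	229636544	229500797	G	T	NM_018230.3:c.472C>A(p.Leu158Ile)	missense	NUP133	Absent	7.759
TOC039	chr1	228433346	228245645	C	T	NM_001386125.1:c.3990C>T(p.Cys1330=)	synonymous	OBSCN	2.52e-03	0.761
TOC039	chr6	143795919	143474782	A	G	NM_003630.3:c.748-4A>G	splice	PEX3	1.85e-05	8.787
TOC047	chr2	219205501	218340778	C	T	NM_015488.5:c.516C>T(p.His172=)	synonymous	PNKD	0.00	12.52
TOC046	chr8	30890266	31032750	G	A	NM_001323311.2:c.33C>T(p.Gly11=)	synonymous	PURG	7.33e-06	13.33
TOC046	chr20	20552120	20571476	T	C	NM_020343.4:c.3138A>G(p.Gly1046=)	synonymous	RALGAPA2	Absent	11.94
TOC069	chr14	23817468	23348259	C	T	NM_016609.7:c.1073G>A(p.Arg358Gln)	missense	SLC22A17	2.46e-05	23.4
TOC003	chr1	48877209	48411537	G	A	NM_019073.4:c.332C>T(p.Pro111Leu)	missense	SPATA6	6.03e-05	27.9
TOC026	chr20	42089626	43460986	A	G	NM_006275.6:c.958A>G(p.Lys320Glu)	missense	SRSF6	Absent	22.6
TOC012	chr5	134785360	135449670	C	T	NM_001099221.2:c.270G>A(p.Thr90=)	synonymous	TIFAB	3.64e-05	0.253
TOC005	chr8	23082421	23224908	G	T	NM_003844.4:c.154C>A(p.Arg52=)	synonymous	TNFRSF10A	0.00	7.862
TOC007	chr8	100829947	99817719	G	C	NM_152564.5:c.8277G>C(p.Leu2759=)	synonymous	VPS13B	Absent	7.632
TOC039	chr6	29640964	29673187	G	A	NM_001109809.5:c.924C>T(p.Ile308=)	synonymous	ZFP57	7.62e-06	0.348
TOC070	chr16	88496000	88429592	G	A	NM_001367624.2:c.2122G>A(p.Ala708Thr)	missense	ZNF469	0.00	10.63
TOC003	chr1	247264596	247101294	C	T	NM_001142572.2:c.217G>A(p.Glu73Lys)	missense	ZNF669	0.00	15.16
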