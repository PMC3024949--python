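gene_region	factor_name	site_class	identifier	abbrev_ref	ref_id	chrom	start	end	marker
Oct4	Ronin	R()		Dejosez08	B89	chr17	35643243	35643348
Oct4	Nr1b*/2b*; Rar*/Rxr*	HRE		Nordhoff01; Sylvester94	B59;B90	chr17	35642936	35642955	+
Oct4	Nr6a1/GCNF	DR(0)		Fuhrmann01	B91	chr17	35642943	35642955	+
Oct4	LRH1/Nr5a2	DR(0)		Gu05	B92	chr17	35642943	35642955	+
Oct4	Nr2c1/TR2	DR(1)		Park07	B93	chr17	35642936	35642949	+
Oct4	CoupTF1/Nr2f1			Schoorlemmer94	B94	chr17	35642936	35642949	+
Oct4	CoupTF2/Nr2f2			Schoorlemmer94	B94	chr17	35642936	35642949	+
Oct4	SF1	RARE	(a)	Barnea00	B95	chr17	35642936	35642954	+
Oct4	Ear2/Nr2f6			Schoorlemmer94	B94	chr17	35642936	35642949	+
Oct4	Sp1/3			Nordhoff01	B59	chr17	35642929	35642939	+
Oct4	Zfp206			Yu09	B96	chr17	35642877	35642886	+
Oct4	SF1		(b)	Barnea00	B95	chr17	35642769	35642792	+
Oct4	Nobox			Choi06	B97	chr17	35642612	35642618	+
Oct4	LRH1/Nr5a2	1B	PE2	Gu05	B92	chr17	35642109	35642118	+
Oct4	Esrrb		P1	Zhang08	B66	chr17	35642104	35642123	+
Oct4	Nanog		P1	Zhang08	B66	chr17	35642033	35642054	+
Oct4	LRH1/Nr5a2	1B	PE1	Gu05	B92	chr17	35642048	35642057	+
Oct4	Tcf3		M3	Tam08	B98	chr17	35641942	35641948	+
Oct4	SF1	1A(PE)		Nordhoff01	B99	chr17	35641863	35641873	+
Oct4	demethylation site	1A(PE)		Aoto06	B59;B99	chr17	35641856	35641875	+
Oct4	Esrrb		P2	Zhang08	B66	chr17	35641431	35641450	+
Oct4	Sall4			Zhang06	B100	chr17	35641024	35641063	+
Oct4	OctSox			Chew05	B101	chr17	35640993	35641008	+
Oct4	OctSox	2B		OkumuraN05	B102	chr17	35640987	35641016	+
Oct4	Tcf3		M1	Tam08	B98	chr17	35640793	35640799	+
Oct4	CR2	1B(PE)		Nordhoff01	B59	chr17	35642037	35642063
Oct4	CR4	2A(DE)		Nordhoff01	B59	chr17	35640947	35640965
Oct4	CR1			Nordhoff01	B59	chr17	35642918	35643044
Oct4	CR2			Nordhoff01	B59	chr17	35641981	35642181
Oct4	CR3			Nordhoff01	B59	chr17	35641641	35641746
Oct4	CR4			Nordhoff01	B59	chr17	35640937	35641068
Sox2	NF-Y			Wiebe00	B60	chr3	34548868	34548886	+
Sox2	Lef1, Lef1	neural		Kamachi09	B48	chr3	34564288	34564307	+
Sox2	FGF	neural		Kamachi09	B48	chr3	34564324	34564330	+
Sox2	Oct4/6, Sox			Tomioka02	B82	chr3	34552970	34552985	+
Sox2	Stat3		2	Foshay08	B103	chr3	34548486	34548498	+
Sox2	Stat3		1	Foshay08	B103	chr3	34545179	34545199	+
Sox2	Gli		1	Takanaga09	B104	chr3	34545198	34545206	+
Sox2	Oct4; Brn1/2		1	Catena04	B105	chr3	34545218	34545229	+
Sox2	Oct4; Brn1/2		2	Catena04	B105	chr3	34545293	34545302	+
Sox2	HIF2alpha	HRE	1	MorenoM10	B106	chr3	34547578	34547592	+
Sox2	HIF2alpha	HRE	2	MorenoM10	B106	chr3	34548182	34548196	+
Sox2	Gli		2	Takanaga09	B104	chr3	34545074	34545085	dna_not_matching
Sox2	N1	neural		Kamachi09	B48	chr3	34564105	34564403
Sox2	N2	neural		Kamachi09	B48	chr3	34544940	34545478
Sox2	N3	neural		Kamachi09	B48	chr3	34529134	34529728
Sox2	N4	neural		Kamachi09	B48	chr3	34577673	34578140
Sox2	N5	neural		Kamachi09	B48	chr3	34558702	34559054
Nanog	Oct1			Wu05	B107	chr6	122657427	122657442	+
Nanog	OctSox			Rodda05; Kuroda05	B108;B69	chr6	122657429	122657445	+
Nanog	Smad2/3/4			Greber10	B109	chr6	122657408	122657412	+
Nanog	Klf4	R()		Zhang10	B110	chr6	122657370	122657550
Nanog	Stat			Suzuki06	B111	chr6	122653091	122653100	+
Nanog	T			Suzuki06	B111	chr6	122653135	122653155	+
Nanog	FoxD3			Pan06	B112	chr6	122657311	122657341	+
Nanog	p53		RE1	Lin05	B113	chr6	122656935	122656957	+
Nanog	p53		RE2	Lin05	B113	chr6	122657195	122657221	+
Nanog	Klf			Jiang08	B114	chr6	122652655	122652663	+
Nanog	Sp1/3		2	Wu06	B115	chr6	122657555	122657570	+
Nanog	Sp1/3		1	Wu06	B115	chr6	122657530	122657539	+
Nanog	Tcf3			Pereira06	B116	chr6	122653837	122653844	+
Nanog	Gcnf/Nr6a1			Gu05	B92	chr6	122655499	122655511	+
Nanog	Cdx2 and Nanog	R()		Chen09	B117	chr6	122652629	122652743
Nanog	Zfp143	revcom		Chen08	B118	chr6	122657340	122657354	+
Nanog	Esrrb			vdBerg08	B119	chr6	122657409	122657418	+
Nanog	Klf5			Parisi08	B120	chr6	122657532	122657539	+
Nanog	CR1			Chan09	B84	chr6	122657170	122657827
Nanog	CR2			Chan09	B84	chr6	122652641	122653468
Nanog	CR3			Chan09	B84	chr6	122652431	122652696
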