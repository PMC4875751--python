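species	abbr	order	lrp	asnC	recA	rpoB	rRNA16S
Citrobacter youngae	Cyo	Enterobacteriales	EFE08594.1	EFE06470.1	EFE06891.1	EFE05379.1	AB273741
Dickeya dadantii	Dda	Enterobacteriales	ADM98245.1	WP_038921215.1	WP_013319098.1	WP_038900031.1	AF520707
Escherichia coli	Eco	Enterobacteriales	NP_415409.1	NP_418199.1	AIZ90260.1	NP_418414.1	NR_102804.1
Klebsiella pneumoniae	Kpn	Enterobacteriales	EOZ13501.1	B5XZL3_KLEP3	KFJ75935.1	CDQ52107.1	AF394537
Photorhabdus asymbiotica	Pas	Enterobacteriales	CAQ84933.1	KGM25900.1	CAQ85300.1	CAQ82443.1	NR_029093.1
Proteus mirabilis	Pmi	Enterobacteriales	CAA71443.1	B4F0D6_PROMH	KGY45908.1	KGA91942.1	KM099410.1
Salmonella enterica Typhimurium	Sty	Enterobacteriales	NP_459935.1	NP_462775.1	NP_461750.1	AAF33499.1	DQ344537
Serratia marcescens	Sma	Enterobacteriales	AAA75466.1	KMJ03309.1	WP_015670993.1	KHO40608.1	AF124036
Yersinia enterocolitica	Yen	Enterobacteriales	AJI83973.1	AHM76528.1	AJJ25926.1	AJJ28227.1	NR_074308.1
Yersinia pestis	Ype	Enterobacteriales	CAL20027.1	YP_002345098.1	CAL21898.1	CAL22334.1	NR_074199.1
Grimontia indica	Gin	Vibrionales	WP_002539165.1	WP_002541578.1	WP_002537588.1	EOD77459.1	FJ943235
Photobacterium aphoticum	Pap	Vibrionales	GAL04870.1	GAL07747.1	GAL08267.1	Q6LLW2.1	X74685
Vibrio anguillarium	Van	Vibrionales	AEH33539.1	CDQ51588.1	P26348.1	CDQ49128.1	X71817
Vibrio campbelli	Vca	Vibrionales	KGR35110.1	KGR34405.1	WP_045384581.1	A7MXF1.1	DQ980029
Vibrio cholerae N16961	Vch	Vibrionales	AAF95052.1	NP_229730.1	P45383.1	Q9KV30.2	AE004119
Vibrio fischeri	Vfi	Vibrionales	YP_204287.1	YP_203464.1	YP_203918.1	YP_205797.2	CP000020
Vibrio icthyoenteri	Vic	Vibrionales	EGU46924.1	EGU37343.1	EGU37265.1	EGU40820.1	HM771339
Vibrio splendidus	Vsp	Vibrionales	EAP92110.1	EAP95563.1	WP_029225094.1	WP_029224582.1	AJ515230
Vibrio variabilis	Vva	Vibrionales	KHA61343.1	GAL25042.1	GAL30153.1	KHA59154.1	GU929924
Vibrio vulnificus	Vvu	Vibrionales	BAC94085.1	NP_932862.1	AIL71594.1	KFK71115.1	BA000037
Actinobacillus succinogenes	Asu	Pasteurellales	ABR74465.1	WP_012072259.1	WP_011978916.1	A6VKC5.1	NR_074818.1
Aggregatibacter actinomycetemcomitans	Aac	Pasteurellales	WP_005540269.1	WP_005548336.1	Q9JRP9.1	EKX96954.1	CP003496
Avibacterium paragallinarum	Apa	Pasteurellales	WP_017806582.1	WP_017806647.1	KKB01216.1	KKB02504.1	AY498868
Chelonobacter oris	Cor	Pasteurellales	WP_034612909.1	WP_034615444.1	KGQ69536.1	KGQ69613.1	EU331064
Gallibacterium genomo	Gge	Pasteurellales	WP_039173617.1	WP_013745649.1	KGQ37099.1	WP_039172822.1	AF228015
Haemophilus ducreyi	Hdu	Pasteurellales	WP_010945324.1	WP_041603575.1	AAP95375.1	Q7VKL7.1	M63900
Haemophilus influenzae	Hin	Pasteurellales	KAI97579.1	WP_005649540.1	AJO91526.1	AJO91604.1	M35019
Mannheimia haemolytica	Mha	Pasteurellales	WP_006251058.1	WP_006248981.1	AAD53288.1	AKA12987.1	NR_102832.1
Necropsobacter rosorum	Nro	Pasteurellales	WP_032092886.1	WP_032093497.1	WP_032093315.1	WP_032093555.1	NR_114428.1
Pasteurella multocida	Pmu	Pasteurellales	WP_005721107.1	WP_005718316.1	P95526.1	AAK03821.1	NR_103916.1
Ferrimonas futtsuensis	Ffu	Alteromonadales	WP_028108266.1	WP_028110962.1	WP_028109920.1	WP_028110712.1	AB245515
Ferrimonas senticii	Fse	Alteromonadales	WP_028115272.1	WP_028117739.1	WP_028117049.1	WP_028117235.1	DQ778094
Idiomarina sp. A28L	Isp	Alteromonadales	EGN75753.1	WP_007420625.1	EGN75701.1	EGN75162.1	FJ404759
Moritella dasanensis	Mda	Alteromonadales	WP_017223704.1	WP_017222470.1	WP_017221889.1	WP_017222504.1	EF192283.1
Pseudoalteromonas luteoviolacea	Plu	Alteromonadales	WP_023398863.1	WP_023399751.1	ESP93629.1	KID54553.1	X82144
Pseudoalteromonas tunicata	Ptu	Alteromonadales	WP_009839786.1	WP_009840643.1	WP_009837615.1	EAR26370.1	DQ005908
Psychromonas aquimarina	Paq	Alteromonadales	WP_011771837.1	WP_028864437.1	WP_028864512.1	WP_028863208.1	AB304805
Shewanella frigidimarina	Sfr	Alteromonadales	WP_011637260.1	WP_011636002.1	Q086A0.1	WP_011635633	NR_074814.1
Shewanella loihica	Slo	Alteromonadales	ABO23891.1	WP_014609941.1	ABO23085.1	ABO22023.1	NR_074815.1
Shewanella pealeana	Spe	Alteromonadales	WP_012155470.1	WP_012154000.1	ABV86522.1	A8GYW9.1	NR_074821.1
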