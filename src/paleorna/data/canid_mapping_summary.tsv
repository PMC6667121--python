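# Mapping summary of shotgun RNA libraries from two historical wolf skins,
# three Pleistocene permafrost canid tissues and an extraction blank, each
# sequenced on two platforms. Count columns are per-sample read tallies
# (total post-adapter-trimming, genome-, mRNA-, rRNA- and tRNA-mapped);
# *_printed columns are the derived statistics as published, used to check
# the composition arithmetic round-trips.
platform	sample_id	tissue	total_reads	genome	mrna	rrna	trna	rrna_proportion_printed	enrichment_factor_printed	endogenous_percent_printed
BGISEQ	Skin 1	skin	69053233	26043866	6858947	16714271	4243690	31.03	14.69	37.72
BGISEQ	Skin 2	skin	6675338	5581322	1288462	4696537	354381	39.40	15.62	83.61
BGISEQ	Tumat C	cartilage	44765013	2244289	783522	401982	32077	11.61	7.46	5.01
BGISEQ	Tumat L	liver	27626403	16509691	5038336	3570007	7617698	10.91	13.52	59.76
BGISEQ	Tumat M	muscle	66780343	3815483	1057959	1357348	317792	20.73	9.85	5.71
BGISEQ	Blank	blank	1701272	56822	20808	126467	24069	55.43	41.47	3.34
HiSeq	Skin 1	skin	23258645	11366481	3493902	7612932	1441633	31.83	15.18	48.87
HiSeq	Skin 2	skin	32927602	26320301	5618346	19883788	1990974	36.95	14.36	79.93
HiSeq	Tumat C	cartilage	20915948	2354199	1064732	209067	31676	5.71	7.63	11.26
HiSeq	Tumat L	liver	6811527	4114476	1882220	1192800	796571	14.94	12.94	60.40
HiSeq	Tumat M	muscle	39878232	2932798	1099000	818537	127563	16.44	9.59	7.35
HiSeq	Blank	blank	1339288	75612	91929	9498	1029	5.33	18.63	5.65
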