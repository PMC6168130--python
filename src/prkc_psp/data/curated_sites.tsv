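accession	position	gene	organism	pmids
P16263	182	odhB	Bacillus subtilis	24390483
P38494	365	ypfD	Bacillus subtilis	24390483
P37561	88	yabS	Bacillus subtilis	24390483
P37561	90	yabS	Bacillus subtilis	24390483
P45740	565	thiC	Bacillus subtilis	24390483
P42974	49	ahpF	Bacillus subtilis	24390483
O34948	281	ykwC	Bacillus subtilis	24390483
O34507	162	prkC	Bacillus subtilis	12842463
O34507	163	prkC	Bacillus subtilis	12842463
O34507	165	prkC	Bacillus subtilis	12842463
O34507	167	prkC	Bacillus subtilis	12842463
O34507	214	prkC	Bacillus subtilis	20389117;12842463
O34507	290	prkC	Bacillus subtilis	20389117;12842463
O34507	313	prkC	Bacillus subtilis	20389117;12842463
O34507	320	prkC	Bacillus subtilis	20389117;12842463
O34507	417	prkC	Bacillus subtilis	20389117
O34507	498	prkC	Bacillus subtilis	20389117
P19669	26	tal	Bacillus subtilis	20389117
P19669	54	tal	Bacillus subtilis	20389117
P19669	82	tal	Bacillus subtilis	20389117
P19669	125	tal	Bacillus subtilis	20389117
P19669	159	tal	Bacillus subtilis	20389117
P19669	184	tal	Bacillus subtilis	20389117
P12425	26	glnA	Bacillus subtilis	20389117
P12425	147	glnA	Bacillus subtilis	20389117
P12425	207	glnA	Bacillus subtilis	20389117
P12425	286	glnA	Bacillus subtilis	20389117
P39126	138	icd	Bacillus subtilis	20389117
P39126	147	icd	Bacillus subtilis	20389117
P39126	396	icd	Bacillus subtilis	20389117
Q04777	88	alsD	Bacillus subtilis	20389117
P08877	12	ptsH	Bacillus subtilis	20389117
O34530	166	rsgA	Bacillus subtilis	22544754
O34530	192	rsgA	Bacillus subtilis	19246764
O34530	226	rsgA	Bacillus subtilis	19246764
P33166	385	tuf	Bacillus subtilis	19246764
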