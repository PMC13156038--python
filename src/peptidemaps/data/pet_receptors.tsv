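receptor	system	receptor_class
D2	dopamine	metabotropic
5HT1A	serotonin	metabotropic
5HT1B	serotonin	metabotropic
5HT2A	serotonin	metabotropic
5HT4	serotonin	metabotropic
5HT6	serotonin	metabotropic
A4B2	acetylcholine	ionotropic
M1	acetylcholine	ionotropic
NMDA	glutamate	ionotropic
mGluR5	glutamate	metabotropic
GABAA	GABA	ionotropic
H3	histamine	metabotropic
CB1	cannabinoid	metabotropic
MOR	opioid	metabotropic
KOR	opioid	metabotropic
DAT	dopamine	metabotropic
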