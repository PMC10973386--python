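# Protein id -> species map for the packaged hit-table fixtures.
protein	species
FAP129	Chlamydomonas
FAP222	Chlamydomonas
FAP252	Chlamydomonas
XP_001689677	Chlamydomonas
FAM166A	Human
FAM166B	Human
FAM166C	Human
C10ORF82	Human
SPATA48	Human
TTLL9	Human
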