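# Forward remote-homology hit table for the PYG-repeat search, query FAP129
# (C. reinhardtii).  Target membership is transcribed from the published search
# summary: the four human proteins FAM166A, FAM166B, FAM166C, C10ORF82 and the
# C. reinhardtii MIPs XP_001689677, FAP222, FAP252 appeared among the top
# significant matches.  The publication prints no per-hit E-values, so the
# numeric E-values below are SYNTHETIC placeholders chosen on the significant
# side of the E < 0.01 cutoff (and, for the two control rows, on the failing
# side) purely to exercise the reliability rule.
query	target	evalue
FAP129	FAM166B	1e-7
FAP129	FAM166A	2e-6
FAP129	FAM166C	8e-6
FAP129	C10ORF82	3e-4
FAP129	XP_001689677	5e-8
FAP129	FAP222	1e-5
FAP129	FAP252	4e-5
FAP129	SPATA48	2e-2
FAP129	TTLL9	9e-1
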