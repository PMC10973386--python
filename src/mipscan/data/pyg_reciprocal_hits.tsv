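# Reciprocal hit tables for the PYG-repeat validation: each forward target
# re-used as a search query.  Grouped by the query column.  As with the
# forward table, per-hit E-values are SYNTHETIC placeholders (the publication
# prints none); what matters is that each reciprocal search recapitulates the
# original query FAP129 below the E < 0.01 cutoff.  FAP222 intentionally has
# no reciprocal table (reason code no_reciprocal_search).
query	target	evalue
FAM166B	FAP129	3e-6
FAM166B	FAM166A	1e-9
FAM166A	FAP129	6e-5
FAM166C	FAP129	2e-4
FAM166C	FAM166B	5e-8
C10ORF82	FAP129	9e-4
XP_001689677	FAP129	1e-6
FAP252	FAP129	7e-4
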