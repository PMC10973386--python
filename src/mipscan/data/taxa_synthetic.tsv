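# SYNTHETIC illustrative taxa table for presence/absence (Coulson-style)
# profiling.  The published per-genome occurrence chart spans 52 eukaryotic
# genomes but prints neither the species list nor the per-cell values, so this
# fixture is a small invented panel of well-known ciliated and non-ciliated
# eukaryotes for demonstrations and tests; users supply their own table for
# real analyses.  ciliated: 1 = builds cilia/flagella, 0 = does not.
species	ciliated	group
Homo_sapiens	1	Metazoa
Mus_musculus	1	Metazoa
Danio_rerio	1	Metazoa
Drosophila_melanogaster	1	Metazoa
Chlamydomonas_reinhardtii	1	Viridiplantae
Tetrahymena_thermophila	1	Alveolata
Trypanosoma_brucei	1	Excavata
Naegleria_gruberi	1	Excavata
Saccharomyces_cerevisiae	0	Fungi
Schizosaccharomyces_pombe	0	Fungi
Arabidopsis_thaliana	0	Viridiplantae
Dictyostelium_discoideum	0	Amoebozoa
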