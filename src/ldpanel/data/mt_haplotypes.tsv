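# Mitochondrial haplotype catalog for the bovine low-density array (13 haploid loci).
#loci: BovineHD3200000141,BovineHD3200000145,BovineHD3200000180,BovineHD3200000226,BovineHD3200000252,BovineHD3200000312,BovineHD3200000332,BovineHD3200000342,BovineHD3200000354,BovineHD3200000358,BovineHD3200000368,BovineHD3200000384,BovineHD3200000406
name	haplotype	lineage
1	CCGCAACCGCCCG	taurine-major
2	CCGCAAACGCCCG	taurine-variant
3	CCGCAACAGCCCG	taurine-variant
4	CCGCAACCACCCG	taurine-variant
5	CCGCAACCGCCCA	taurine-variant
6	CAACAACCGCCCG	taurine-variant
7	AAGAGCAAAAAAG	indicine
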