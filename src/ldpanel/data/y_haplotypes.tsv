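# Y-chromosome haplotype catalog for the bovine low-density array (9 haploid loci).
#loci: BovineHD3100000048,BovineHD3100000099,BovineHD3100000103,BovineHD3100000210,BovineHD3100000515,BovineHD3100000517,BovineHD3100001188,BovineHD3100001404,BovineHD3100001406
name	haplotype	lineage
1	CGCCGCAAC	indicine
2	TCTCCTCAC	taurine-central-European
3	TCTCCTCAT	taurine-Jersey-lineage
4	TCTTGTCGC	taurine-northern-European
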