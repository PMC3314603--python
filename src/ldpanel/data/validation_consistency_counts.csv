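statistic,comparison,breed,n_comparisons,n_genotyped,n_inconsistent
mendelian,duo,Angus,2,13636,3
mendelian,duo,Holstein,3,20508,0
mendelian,duo,Jersey,1,6833,0
mendelian,duo,N'Dama,1,6720,0
mendelian,duo,Red Angus,1,6807,1
mendelian,trio,Angus,3,20473,2
mendelian,trio,Beefmaster,1,6803,10
mendelian,trio,Brahman,3,20279,42
mendelian,trio,Brown Swiss,2,13597,0
mendelian,trio,Charolais,3,20325,7
mendelian,trio,Hereford,2,13607,3
mendelian,trio,Holstein,4,27283,2
mendelian,trio,Jersey,3,20438,5
mendelian,trio,Santa Gertrudis,3,20410,43
reproducibility,replicate,Hereford,1,6792,1
reproducibility,replicate,Holstein,4,27320,1
reproducibility,replicate,Jersey,4,6824,2
reproducibility,replicate,Limousin,1,6824,2
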