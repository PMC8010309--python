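age_group,phenotype,genus,dose_mg_kg,cfr_pct
2-6,NM,Aspergillus,12,80.1
2-6,NM,Candida,6,80.2
2-6,IM,Aspergillus,8,80.9
2-6,IM,Candida,5,90.0
2-6,PM,Aspergillus,5,86.0
2-6,PM,Candida,3,91.9
6-12,NM,Aspergillus,9,82.0
6-12,NM,Candida,4,82.4
6-12,IM,Aspergillus,6,84.9
6-12,IM,Candida,3,82.0
6-12,PM,Aspergillus,4,88.6
6-12,PM,Candida,2,88.4
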