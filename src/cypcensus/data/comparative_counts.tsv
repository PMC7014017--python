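taxon	species_analyzed	p450s	families	subfamilies	bgcs	bgc_types	p450s_in_bgcs	dominant_family
Cyanobacteria	114	341	36	79	770	73	27	CYP110
Bacillus	128	507	13	28	1098	33	112	CYP107
Mycobacteria	60	1784	77	132	898	18	204	CYP125
Streptomyces	48	1625	144	377	1461	159	554	CYP107
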