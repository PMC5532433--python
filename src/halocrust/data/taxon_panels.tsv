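panel	taxonomy	total_populations	site_specific_pct	sample_specific_pct	wet_only_pct	intermediate_only_pct	dry_only_pct	all_sites_pct	wet_intermediate_pct	intermediate_dry_pct	dry_wet_pct
A	Halobacteriales	65	63	8	3	3	14	43	28	3	6
A	Bacteroidetes	31	45	0	13	23	10	45	0	6	3
A	Parcubacteria (OD1)	4	100	100	75	25	0	0	0	0	0
A	Actinobacteria	2	0	0	0	0	0	0	0	0	100
A	Nanohaloarchaea	5	100	100	80	20	0	0	0	0	0
A	Cyanobacteria	3	67	0	33	0	33	33	0	0	0
A	Thermoplasmatales	1	100	100	100	0	0	0	0	0	0
A	Proteobacteria	1	100	0	100	0	0	0	0	0	0
A	Saccharibacteria (TM7)	3	100	100	33	0	67	0	0	0	0
B	Halobacteriales	148	86	75	33	22	31	3	5	3	2
B	Bacteroidetes	23	65	43	30	26	9	17	4	9	4
B	Parcubacteria (OD1)	10	100	100	40	50	10	0	0	0	0
B	Actinobacteria	3	67	67	33	0	33	0	0	0	33
B	Nanohaloarchaea	6	100	100	100	0	0	0	0	0	0
B	Cyanobacteria	3	67	0	33	0	33	33	0	0	0
B	Thermoplasmatales	1	100	100	100	0	0	0	0	0	0
B	Proteobacteria	3	100	100	67	0	33	0	0	0	0
B	Saccharibacteria (TM7)	1	0	0	0	0	0	0	0	0	100
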