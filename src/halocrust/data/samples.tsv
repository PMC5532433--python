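sample_id	site_id	plot_id	distance_from_coast_km	wetness_hours	latitude	longitude
Sw1	Sw	Sw_p1	25.5	3113	-21.210	-69.952
Sw2	Sw	Sw_p1	25.5	3113	-21.210	-69.952
Sw3	Sw	Sw_p1	25.5	3113	-21.210	-69.952
Sw4	Sw	Sw_p2	25.5	3113	-21.210	-69.952
Sw5	Sw	Sw_p2	25.5	3113	-21.210	-69.952
Sw6	Sw	Sw_p2	25.5	3113	-21.210	-69.952
Sw7	Sw	Sw_p3	25.5	3113	-21.210	-69.952
Sw8	Sw	Sw_p3	25.5	3113	-21.210	-69.952
Sw9	Sw	Sw_p3	25.5	3113	-21.210	-69.952
Qh1	Qh	Qh_p1	44.1	1560	-21.268	-69.774
Qh2	Qh	Qh_p1	44.1	1560	-21.268	-69.774
Qh3	Qh	Qh_p1	44.1	1560	-21.268	-69.774
Qh4	Qh	Qh_p2	44.1	1560	-21.268	-69.774
Qh5	Qh	Qh_p2	44.1	1560	-21.268	-69.774
Qh6	Qh	Qh_p2	44.1	1560	-21.268	-69.774
Qh7	Qh	Qh_p3	44.1	1560	-21.268	-69.774
Qh8	Qh	Qh_p3	44.1	1560	-21.268	-69.774
Qs1	Qs	Qs_p1	54.2	891	-21.304	-69.676
Qs2	Qs	Qs_p1	54.2	891	-21.304	-69.676
Qs3	Qs	Qs_p1	54.2	891	-21.304	-69.676
Qs4	Qs	Qs_p2	54.2	891	-21.304	-69.676
Qs5	Qs	Qs_p2	54.2	891	-21.304	-69.676
Qs6	Qs	Qs_p2	54.2	891	-21.304	-69.676
Qs7	Qs	Qs_p3	54.2	891	-21.304	-69.676
Qs8	Qs	Qs_p3	54.2	891	-21.304	-69.676
Qs9	Qs	Qs_p3	54.2	891	-21.304	-69.676
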