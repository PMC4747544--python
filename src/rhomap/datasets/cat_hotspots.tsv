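hotspot_id	chrom	start	end	size_kb	n_bins	mean_pp	mean_bf	mean_gc
A2_1	A2	98237700	98240700	3.0	15	0.54	339.85	0.35
D1_1	D1	50430400	50432200	1.8	9	0.56	271.90	0.38
E2_1	E2	42987500	42989300	1.8	9	0.54	418.27	0.40
E2_2	E2	43026700	43031300	4.6	23	0.65	293.30	0.42
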