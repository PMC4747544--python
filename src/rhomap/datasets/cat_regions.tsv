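chrom	n_snps	start	end	mean_rho_per_mb	bins_lt100	bins_ge100	bins_total
A1	53	187299691	188082901	127.68	3915	0	3915
A2	73	98172535	98956464	186.51	3904	15	3919
B3	88	126081886	126859181	202.67	3886	0	3886
C2	53	4360303	5085917	291.85	3628	0	3628
D1	70	50348845	51177183	176.72	4131	10	4141
D2	86	59655061	60470312	192.93	4074	0	4074
D4	73	45514026	46304562	259.47	3951	0	3951
E2	90	42987235	43794319	309.48	4002	32	4034
F2	78	10965562	12451350	185.95	7427	0	7427
X	37	100018322	100740914	77.45	3613	0	3613
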