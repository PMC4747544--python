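hotspot_id	repeat_class	name
A2_1	LINE	L1MEg
A2_1	SINE	SINEC-Fc2
A2_1	SINE	MIR
A2_1	SINE	MIRb
A2_1	Low_complexity	AT-rich
A2_1	DNA	MER46C
D1_1	LINE	L2a
D1_1	SINE	SINEC-Fc2
D1_1	SINE	MIRb
D1_1	SINE	MIRb
D1_1	LTR	MLT1J
D1_1	Simple_repeat	(TA)n
E2_1	LINE	L2a
E2_1	SINE	MIR3
E2_2	LINE	L2b
E2_2	LINE	L2b
E2_2	LINE	L2a
E2_2	SINE	SINEC-Fc2
E2_2	SINE	MIR
E2_2	Simple_repeat	(GA)n
E2_2	Simple_repeat	(TG)n
E2_2	DNA	MER20
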