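protein_id	tm_index	start	end	topology
P21554	1	117	142	extracellular
P21554	2	155	175	extracellular
P21554	3	188	212	extracellular
P21554	4	233	255	extracellular
P21554	5	274	299	extracellular
P21554	6	345	365	extracellular
P21554	7	378	399	extracellular
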