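# Printed field observations for the catalog designs.
# columns: design_id, class, count
design_id	class	count
D2	full	122
D2	low	118
D3	full	105
D3	low	0
D4	all-donor	88
D4	recombinant	0
D6	full	104
D6	low	116
D7	full	167
D7	none	21
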