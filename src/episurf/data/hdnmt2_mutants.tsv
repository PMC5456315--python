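label	chain	pos	wt	target
Mutant-I	A	295	K	A
Mutant-II	A	122	K	A
Mutant-III	A	289	R	A
Mutant-IV	A	371	R	A
Mutant-V	A	367	K	A
Mutant-VI	A	275	R	A
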