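label	chain	pos	wt	target
R225A	A	225	R	A
T29	A	225	R	A
T29	A	260	N	L
T29	A	261	L	M
T29	A	262	N	W
T7	A	225	R	A
T7	A	260	N	L
T7	A	261	L	F
T7	A	262	N	W
T28	A	225	R	A
T28	A	260	N	L
T28	A	261	L	S
T28	A	262	N	W
T26	A	225	R	A
T26	A	260	N	L
T26	A	261	L	T
T26	A	262	N	W
T45	A	225	R	A
T45	A	260	N	L
T45	A	261	L	W
T45	A	262	N	W
T1	A	225	R	A
T1	A	260	N	L
T1	A	261	L	R
T1	A	262	N	W
T40	A	225	R	A
T40	A	260	N	L
T40	A	261	L	C
T40	A	262	N	W
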