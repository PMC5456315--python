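label	kcat_km
HaeIII	2.60E+04
HhaI	1.20E+07
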