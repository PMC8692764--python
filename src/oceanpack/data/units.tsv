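from_curie	to_curie	factor	offset
UO:0000062	UO:0000063	1000	0
UO:0000063	UO:0000064	1000	0
UO:0000064	UO:0000065	1000	0
UO:0000027	UO:0000012	1	273.15
UO:0010004
UO:0000185
UO:0000008
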