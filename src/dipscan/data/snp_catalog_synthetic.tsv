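reference	position	alt
AMP1	50	T
AMP1	120	A
AMP2	77	G
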