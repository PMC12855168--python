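strain	role	n_active_0mM	n_active_300mM
MO56(1)	tolerant	108	61
BO21CC	tolerant	94	58
RU11/001	sensitive	86	53
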