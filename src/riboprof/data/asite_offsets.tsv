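read_length	asite_offset
28	15
29	15
30	15
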