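category	panel	tested	positive
low	Sanger-Test	418	13
low	NGS-Test	120	23
high	Sanger-Test	268	67
high	NGS-Test	82	25
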