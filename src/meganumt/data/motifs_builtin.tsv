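haplogroup	parent	variants
root
HV0	root	72C 200G 16298C
V	HV0	4580A
U4c1	root	73G 189G 195C 499A 16179T 16356C 16512C 16519C
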