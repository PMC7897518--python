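id	father	mother	sex	status
I.1	0	0	M	non_carrier
I.2	0	0	F	non_carrier
II.1	0	0	M	non_carrier
II.2	I.1	I.2	F	carrier
III.1	0	0	M	non_carrier
III.2	II.1	II.2	F	carrier
III.3	0	0	M	non_carrier
III.4	II.1	II.2	F	carrier
III.5	0	0	M	non_carrier
III.6	II.1	II.2	F	non_carrier
IV.1	III.1	III.2	M	carrier
IV.2	0	0	F	non_carrier
IV.3	III.1	III.2	F	carrier
IV.4	III.3	III.4	F	carrier
IV.5	III.3	III.4	F	carrier
IV.6	III.3	III.4	F	carrier
IV.7	III.5	III.6	M	non_carrier
V.1	IV.1	IV.2	M	unknown
V.2	IV.1	IV.2	F	non_carrier
V.3	IV.1	IV.2	M	unknown
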