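chr	pos	cm
1	500	0.0
1	1500	1.0
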