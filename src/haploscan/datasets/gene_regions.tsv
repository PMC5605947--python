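gene	chrom	start	end
BDNF	11	27020461	27990119
DAOA	13	106065361	106393146
APOE	19	45290685	45548502
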