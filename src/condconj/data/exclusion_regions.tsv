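chrom	start	end	label
6	25652429	33368333	MHC
8	7242715	12483982	8p23.1
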