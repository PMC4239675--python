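sample	chrom	start	end	value
toy	chr1	1	200000	2
toy	chr1	200001	1000000	1
toy	chr2	1	1000000	2
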