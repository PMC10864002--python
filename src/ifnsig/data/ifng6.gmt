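IFNG-6	six-gene IFN-gamma comparator signature	IDO1	CXCL10	CXCL9	HLA-DRA	STAT1	IFNG
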