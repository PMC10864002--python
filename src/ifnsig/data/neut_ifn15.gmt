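Neut_IFN-15	IFN-stimulated neutrophil signature	IFIT1	MX1	HERC5	IFI6	ISG15	IFIT3	RSAD2	GBP1	IFIT2	XAF1	PARP9	UBE2L6	IRF7	PARP14	APOL6
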