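interferon_alpha_response	na	IFIT1	IFIT3	MX1	MX2	ISG15	IFI6	IFI27	IFI35	IFI44	RSAD2	IRF7	IRF9	OAS1	OASL	USP18	HERC5	HERC6	SAMD9	BST2	LY6E	CMPK2	PARP9	UBE2L6
interferon_gamma_response	na	STAT1	STAT2	IRF1	GBP1	GBP2	CXCL9	CXCL10	CXCL11	IDO1	ISG15	IFIT2	XAF1	PARP14	SOCS1	TAP1	PSMB9	HLA-DRA	IRF7	APOL6	MX1
tnfa_signalling_via_nfkb	na	NFKB1	NFKBIA	TNF	TNFAIP3	CXCL1	CXCL2	IL1B	IL6	JUN	JUNB	FOS	FOSB	IER2	IER3	EGR1	CCL2	SOCS3	PTGS2	TRAF1	RELB
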