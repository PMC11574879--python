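iCAF	inflammatory fibroblast signature (literature-derived placeholder list; replace with study-specific lists when available)	IL6	CXCL1	CXCL2	CXCL12	CXCL14	CCL2	PDGFRA	CFD	DPT	LMNA	HAS1	HAS2	CLU	EMP1	IGF1	C3	C7
myCAF	myofibroblastic fibroblast signature (literature-derived placeholder list; replace with study-specific lists when available)	ACTA2	TAGLN	MYL9	MYH11	TPM1	TPM2	POSTN	MMP11	HOPX	CTHRC1	COL12A1	PDGFRB	CALD1	TNC
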