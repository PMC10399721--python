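ligand	receptor	source
CSF2	CSF2RA	iuphar
CSF2	CSF2RB	iuphar
VEGFA	FLT1	iuphar
VEGFA	KDR	iuphar,dlrp
CSF1	CSF1R	iuphar
IL6	IL6RA	dlrp
TGFB1	TGFBR1	dlrp
TGFB1	TGFBR2	dlrp
CCL5	CCR5	iuphar
CXCL10	CXCR3	iuphar
CXCL9	CXCR3	iuphar
TNF	TNFRSF1A	dlrp
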