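GO:1903047	mitotic cell cycle process	SEPT7	KLHL42	CDK5RAP2	CHAMP1	PAPD5	GSPT1	ORC4	CD2AP	SPDL1	MUS81	GSG2	KIF2A	MAP4	PIBF1	CNOT11	PPM1D	USP16	SPAST	ESPL1	ID2	PSMB3	CDCA5	EIF4E	PSMA5	PBRM1	SMC5	EML4	PSMB6	CHMP5	PSMC5	MAP10	RAD17	CACUL1	PSMC1	NOLC1	FBXW11	CEP152	DYNLT3	PSMD7	INTS3	LMNA	SMC4	PSMD2	PSMD12	CEP250	PSMD11	CUL5	MSH2	RAN	PSMD13	TAF10	FBXL15	NIPBL	TUBA1A	MYH10	MIS12	CCNG2	CEP70	MAP9	CCNG1	VPS4B	MYBL2	TOP2B	TFDP2	TOP2A	CLTA	TUBB4B	HMGA2	RPS6KB1	CDK6	DYNC1H1	RBBP8	DYNC1I2	BABAM1	RAB11A	CDK7	DNM2	OFD1	STAG2	CEP192	NDC80	NDC1	NR3C1	HELLS	RUVBL1	CSNK1A1	CCNB1	KIF23	NUDC	CDCA2	HMMR	NUP153	ZNF207
GO:0006325	chromatin organization	ZMYND8	SMARCAD1	VPS72	GSG2	ARID5B	TLK1	BAHD1	NCOR1	PRMT6	KDM5B	SUPT5H	SIRT5	MTA1	USP16	BPTF	DOT1L	KAT2A	BRD8	CHD2	USP7	UTP3	WHSC1	PBRM1	TTF1	PER1	TET3	SCMH1	MTA2	NUCKS1	CREBBP	MORF4L1	CENPP	WDR82	TAF10	MTF2	TAF5	SUPT16H	INO80C	SUPT7L	DNAJC2	HIRA	NFE2	SMARCE1	BRD2	ATRX	RNF2	ATXN7L3	BAZ1A	BAZ1B	HMGA2	PHF20	SMARCC1	PRDM2	BABAM1	SRPK1	OGT	ARID4A	TET2	HIRIP3	CBX3	SMARCA2	NR3C1	HELLS	RUVBL1	SETD2	TLK2	CCNB1	RBM14	KAT6B	PRKCD	ZNF462	ELP3
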