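ASTRO_COMPONENT_1	synthetic stand-in astrocyte component list	GFAP	AQP4	S100B	ALDH1L1	SLC1A2	SLC1A3	GJA1	SOX9	ALDOC	CLU	APOE	GLUL	FGFR3	MLC1	NTSR2
ASTRO_COMPONENT_2	synthetic stand-in astrocyte component list	AQP4	SLC1A2	GJB6	SLC4A4	ATP1B2	ACSBG1	CBS	BMPR1B	PAX6	HEPACAM	GPR37L1	F3	SOX9	EDNRB	PLTP
ASTRO_COMPONENT_3	synthetic stand-in astrocyte component list	GFAP	ALDH1L1	SLC39A12	PPP1R3C	AGT	CHRDL1	RYR3	SLC14A1	ATP13A4	GRIN2C	PRODH	FAM107A	ETNPPL	CLDN10	MGST1
ASTRO_COMPONENT_4	synthetic stand-in astrocyte component list	SLC1A3	GJA1	CLU	SPARCL1	ID4	TTYH1	PLA2G7	SLC7A10	SLC25A18	FGFR3	GPC5	LRIG1	NWD1	PON2	MT1G
ASTRO_COMPONENT_5	synthetic stand-in astrocyte component list	S100B	APOE	CST3	PTGDS	HES5	SOX21	TIMP3	DTNA	ALDOC	PCDHGC3	AHCYL1	ACOT11	TPD52L1	PREX2	KCNN3
ASTRO_COMPONENT_6	synthetic stand-in astrocyte component list	GLUL	MLC1	SLC6A11	SLC6A1	BCAN	GRIA1	GABRG1	KCNJ10	PAPLN	DAAM2	MERTK	CPE	NCAN	PLCD4	GRM3
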