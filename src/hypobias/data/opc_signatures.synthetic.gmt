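OPC_ENRICHED_300	synthetic stand-in OPC-enriched list	PDGFRA	CSPG4	OLIG1	OLIG2	SOX10	LHFPL3	GPR17	DLL3	NKX2-2	PCDH15	MEGF11	CNTN1	SHC4	SCRG1	CA10	BCAS1	SEMA5A	NEU4	MMP15	CHST11
OPC_SPECIFIC_300	synthetic stand-in OPC-specific list	PDGFRA	LHFPL3	PCDH15	CSPG4	SOX10	GPR17	EPN2	C1QL1	SUSD5	RLBP1	FERMT1	ZNF488	SERINC5	LPPR1	TMEM255B	SLC22A3	KANK1	TNR	VCAN	PTPRZ1
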