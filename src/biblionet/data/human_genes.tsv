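# Synthetic gene dictionary fixture: gene_id <TAB> symbol <TAB> tax_id
# Hand-built fixture mimicking an NCBI Gene excerpt; includes two murine
# entries (tax 10090) so the human-only filter is exercised.
59272	ACE2	9606
7113	TMPRSS2	9606
3569	IL6	9606
7124	TNF	9606
5045	FURIN	9606
3627	CXCL10	9606
4938	OAS1	9606
4939	OAS2	9606
4940	OAS3	9606
9636	ISG15	9606
10410	IFITM3	9606
51284	TLR7	9606
3586	IL10	9606
1401	CRP	9606
1803	DPP4	9606
3455	IFNAR2	9606
7297	TYK2	9606
1234	CCR5	9606
3553	IL1B	9606
6772	STAT1	9606
3665	IRF7	9606
4599	MX1	9606
114548	NLRP3	9606
7421	VDR	9606
348	APOE	9606
1636	ACE	9606
6347	CCL2	9606
3458	IFNG	9606
5743	PTGS2	9606
7040	TGFB1	9606
70008	Ace2	10090
50528	Tmprss2	10090
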