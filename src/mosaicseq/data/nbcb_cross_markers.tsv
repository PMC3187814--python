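marker	methodology	CBS7001	NBRC1948	NBCB-2a	NBCB-2b	NBCB-2c	NBCB-2d	NBCB-6a	NBCB-6b	NBCB-6c	NBCB-6d	CBS380T	NRRLY-1551
Contig cB	Hybridization	-	cB	cB	-	-	cB	-	cB	-	cB	cB	cB
Contig cA	Hybridization	-	cA	cA	-	cA	-	-	-	cA	cA	cA	cA
Contig cC	Hybridization	-	cC	-	cC	cC	-	cC	-	-	cC	cC	cC
SuMEL	PCR or sequencing	+	-	-	+	+	-	-	+	-	+	+	+
HO	Sequencing	UVA	LG	UVA	UVA	LG	LG	UVA	LG	UVA	LG	LG	LG
ScBIO2	PCR	-	+	+	-	-	+	-	+	-	+	+	+
ScMAL31 specific fragment	PCR	-	+	+	-	-	+	-	+	-	+	+	+
MTY1 specific fragment	PCR	-	+	+	+	+	-	+	-	+	+	+	+
ScMAL33	PCR	-	+	+	+	+	+	+	+	-	+	+	+
ScBIO2-ScIMA1	PCR	-	+	+	-	-	+	-	+	-	+	+	+
ScIMA1-ScMAL33	PCR	-	+	+	+	+	+	+	+	+	+	+	+
ScMAL33-(MTY1-ScMAL31)	PCR	-	+	+	+	+	+	+	+	-	+	+	+
(MTY1-ScMAL31)-ScMAL32	PCR	-	+	+	+	+	+	+	+	+	+	+	+
ScMAL32-ScCOS2	PCR	-	+	+	+	+	+	+	+	+	+	+	+
ScCOS2-ScSUC4	PCR	-	+	+	+	+	+	+	+	+	+	+	+
ScSUC4-ScRTM1	PCR	-	+	+	-	-	+	+	+	+	+	+	+
Contig cE	PCR	-	+	-	E	-	E	E	-	E	-	+	+
NTS2 patterns	PCR-RFLP	UVAR	CARB	UVAR	CARB	CARB	UVAR	UVAR	UVAR	CARB	CARB	CARB	CARB
PMA1	PCR-RFLP	UVA	LG	UVA	UVA	LG	LG	UVA	LG	UVA	LG	UVA	LG
MAL locus	Sequencing	-	MAL31/MTY1	ND	MTY1	ND	MAL31	MTY1	MAL31	MTY1	ND	MAL31/MTY1	MAL31/MTY1
Melibiose fermentation	Fermentation	+	+	-	+	+	-	-	+	-	+	-	+
Maltotriose fermentation	Fermentation	-	+	+	+	+	-	+	-	+	+	+	+
Maltose fermentation	Fermentation	+	+	+	delay	delay	+	-	+	delay	+	+	+
Sporulation	Phenotype	+	+	+	+	+	+	-	+	+	+	+	-
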