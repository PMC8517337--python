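panel	side	protein_id
exosome_markers	EXOSOME	CD63
exosome_markers	EXOSOME	CD81
exosome_markers	EXOSOME	CD9
exosome_markers	EXOSOME	FLOT1
exosome_markers	EXOSOME	PDCD6IP
exosome_markers	EXOSOME	SDCBP
exosome_markers	EXOSOME	TSG101
exosome_markers	EXOSOME	YWHAE
exosome_markers	EXOSOME	HSPA8
exosome_markers	EXOSOME	HSP90AA1
ectosome_markers	ECTOSOME	ACTB
ectosome_markers	ECTOSOME	ACTN4
ectosome_markers	ECTOSOME	MYLK
ectosome_markers	ECTOSOME	TPM3
ectosome_markers	ECTOSOME	SELP
ectosome_markers	ECTOSOME	ARF6
ectosome_markers	ECTOSOME	MMP9
ectosome_markers	ECTOSOME	ITGB1
ectosome_markers	ECTOSOME	IMMT
ectosome_markers	ECTOSOME	ANXA1
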