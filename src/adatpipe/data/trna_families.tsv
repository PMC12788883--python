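family_id	amino_acid	anticodon	edited
tRNA-Ala-AGC	Ala	AGC	1
tRNA-Arg-ACG	Arg	ACG	1
tRNA-Ile-AAT	Ile	AAT	1
tRNA-Leu-AAG	Leu	AAG	1
tRNA-Pro-AGG	Pro	AGG	1
tRNA-Ser-AGA	Ser	AGA	1
tRNA-Thr-AGT	Thr	AGT	1
tRNA-Val-AAC	Val	AAC	1
tRNA-Ala-CGC	Ala	CGC	0
tRNA-Ala-TGC	Ala	TGC	0
tRNA-Arg-CCG	Arg	CCG	0
tRNA-Arg-TCG	Arg	TCG	0
tRNA-Arg-CCT	Arg	CCT	0
tRNA-Arg-TCT	Arg	TCT	0
tRNA-Asn-GTT	Asn	GTT	0
tRNA-Asp-GTC	Asp	GTC	0
tRNA-Cys-GCA	Cys	GCA	0
tRNA-Gln-CTG	Gln	CTG	0
tRNA-Gln-TTG	Gln	TTG	0
tRNA-Glu-CTC	Glu	CTC	0
tRNA-Glu-TTC	Glu	TTC	0
tRNA-Gly-GCC	Gly	GCC	0
tRNA-Gly-CCC	Gly	CCC	0
tRNA-Gly-TCC	Gly	TCC	0
tRNA-His-GTG	His	GTG	0
tRNA-Ile-TAT	Ile	TAT	0
tRNA-Leu-CAG	Leu	CAG	0
tRNA-Leu-TAG	Leu	TAG	0
tRNA-Leu-CAA	Leu	CAA	0
tRNA-Leu-TAA	Leu	TAA	0
tRNA-Lys-CTT	Lys	CTT	0
tRNA-Lys-TTT	Lys	TTT	0
tRNA-Met-CAT	Met	CAT	0
tRNA-Phe-GAA	Phe	GAA	0
tRNA-Pro-CGG	Pro	CGG	0
tRNA-Pro-TGG	Pro	TGG	0
tRNA-Ser-CGA	Ser	CGA	0
tRNA-Ser-TGA	Ser	TGA	0
tRNA-Ser-GCT	Ser	GCT	0
tRNA-Thr-CGT	Thr	CGT	0
tRNA-Thr-TGT	Thr	TGT	0
tRNA-Trp-CCA	Trp	CCA	0
tRNA-Tyr-GTA	Tyr	GTA	0
tRNA-Val-CAC	Val	CAC	0
tRNA-Val-TAC	Val	TAC	0
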