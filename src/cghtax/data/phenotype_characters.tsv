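character	BL263	BL301	BL302	BL303	BL304	BL17	BL279	BL280	BL221	BL278	BL223	BL277	BL292	BL294	BL296	BL260	BL288	BL261	BL281	BL287	BL295	BL297	BL298	BL299	BL262	BL259
L-Arabinose	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	d	d
Ribose	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	d	d
D-Xylose	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	d
Galactose	-	-	-	-	d	-	+	+	+	-	+	+	-	+	-	-	+	d	d	+	d	-	-	d	+	+
D-Fructose	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	d	+	+	-
D-Mannose	+	+	+	+	+	+	+	+	d	-	+	+	-	+	+	+	+	+	d	+	+	+	d	+	+	-
Mannitol	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	d	+	-	-	-	-	-	-	-	+	-
alpha-methyl-D-Glucoside	-	-	-	-	-	-	-	d	d	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
N-Acetyl-Glucosamine	-	d	+	-	+	+	+	+	+	+	+	+	+	+	+	+	+	d	d	+	+	+	+	+	+	-
Amygdalin	-	-	-	-	-	+	+	+	-	-	+	+	-	+	+	-	-	-	-	-	-	-	-	-	-	-
Arbutin	-	-	-	-	-	-	-	-	d	+	+	+	+	-	+	-	-	-	-	-	-	-	-	-	+	-
Aesculin	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	-	-	d	-	+	+	+	+	+	+	-
Salicin	-	-	-	-	-	+	+	d	d	+	+	+	d	+	+	-	-	-	-	-	d	d	-	-	+	-
Cellobiose	+	d	+	+	+	+	+	d	+	+	+	+	+	+	-	-	-	-	-	d	d	+	+	-	+	-
Maltose	+	+	+	+	+	+	+	+	+	+	+	+	d	+	+	+	+	+	+	+	+	+	-	+	+	+
D-Lactose	-	-	-	-	-	+	+	+	+	-	+	+	-	+	-	-	-	-	-	d	d	+	+	-	+	+
Melibiose	-	-	-	-	-	-	-	d	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	+
Trehalose	+	-	+	+	+	+	+	+	+	-	+	+	+	+	+	-	-	+	+	-	+	+	+	-	+	-
D-Raffinose	-	-	-	-	-	d	+	+	d	-	-	-	-	-	-	-	d	-	-	+	+	-	-	+	+	+
Starch	-	-	-	-	-	-	-	-	+	+	+	+	-	-	-	-	-	d	d	d	d	d	-	-	-	-
Glycogen	-	-	-	-	-	-	-	-	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
beta-Gentibiose	d	-	+	+	+	+	+	+	d	-	+	+	+	+	+	-	-	+	-	+	+	+	-	+	+	-
D-Turanose	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	d	-
D-Tagatose	-	-	-	-	-	-	-	-	-	-	+	+	d	+	-	-	-	-	d	d	-	d	-	-	-	-
Growth 15C	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	+	-	-
Growth 45C	-	-	-	-	-	-	-	-	-	-	-	+	-	+	+	-	-	-	-	-	-	+	+	+	-	-
Growth 4.5% NaCl	-	-	-	-	-	+	-	-	-	-	+	+	-	-	-	-	-	+	+	+	-	+	-	-	+	-
Growth 7.0% NaCl	-	-	-	-	-	-	-	-	-	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Growth pH 4.5	+	+	+	+	+	-	-	-	+	-	+	+	+	+	+	+	+	+	-	+	+	+	+	+	-	+
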