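strain	subspecies	Galactose	D-glucose	D-fructose	D-mannose	N-acetylglucosamine	Amygdalin	Arbutin	Esculin	Salicin	Cellobiose	Maltose	Lactose	Sucrose	Trehalose
CNRZ226	lactis	-	+	+	+	+	+	+	+	+	+	+	-	+	+
CNRZ327	lactis	-	+	+	+	+	-	-	+	-	-	-	+	-	-
CNRZ333	lactis	+	+	+	+	+	-	+	+	+	-	+	+	+	+
CNRZ700	lactis	+	+	-	+	+	-	-	+	-	-	-	+	-	+
ATCC 11842	bulgaricus	-	+	-	+	-	-	-	-	-	-	-	+	-	-
ATCC BAA-365	bulgaricus	-	-	-	+	-	-	-	-	-	-	-	+	-	-
VIB27	bulgaricus	-	+	-	+	-	-	-	+	-	-	-	+	-	-
VIB44	bulgaricus	-	-	-	+	-	-	-	-	-	-	-	+	-	-
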