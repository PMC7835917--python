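mz	formula	name
61.0295	C2H4O2H+	Acetic acid
73.0649	C4H8OH+	Butanone/Butanal
33.0339	CH4OH+	Methanol
48.0534	Isotope of C2H6OH+	Ethanol (isotopologue)
57.0404	C3H4OH+	General fragment
60.0527	Isotope of C3H6OH+	Acetone (isotopologue)
31.0183	CH2OH+	Formaldehyde
43.0182	C2H3O+	General fragment
43.0545	C3H7+	General fragment
41.0384	C3H5+	General fragment
57.0702	C4H9+	Butanol fragment
39.0226	C3H3+	General fragment
87.0445	C4H6O2H+	Diacetyl
89.0599	C4H8O2H+	Ethyl acetate
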