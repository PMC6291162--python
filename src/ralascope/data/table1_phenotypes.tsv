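proband_id	length_at_birth_le10pct	weight_at_birth_le10pct	height_at_last_exam_le10pct	weight_at_last_exam_le10pct	autism_spectrum_disorder	hypotonia	able_to_walk	facial_dysmorphism	seizures
Proband1	-	-	+	+	+	-	+	+	+
Proband2	-	-	-	+	+	+	-	+	-
Proband3	-	-	+	+	+	+	+	-	-
Proband4	+	+	+	+	NR	+	-	+	+
Proband5	+	-	+	+	NR	+	-	+	+
Proband6	NR	NR	NR	+	NR	+	-	+	+
Proband7	-	-	-	+	NR	+	-	+	-
Proband8	NR	-	+	+	NR	+	-	-	+
Proband9	-	-	-	-	NR	+	+	+	-
Proband10	-	-	-	-	NR	+	-	+	-
Proband11	+	+	+	-	NR	+	-	+	+
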