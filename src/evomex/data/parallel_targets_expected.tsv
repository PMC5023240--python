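target	F1	F2	F3	F4	F5	F6	F7	F8
ATP_synthase	+	-	+	-	-	-	-	-
META1_3102	-	-	-	-	-	-	+	+
META1_4902	+	-	+	+	-	-	-	-
META2_0008	-	-	+	-	+	-	-	-
gshA	-	+	+	+	+	+	-	-
icuAB	+	+	+	+	-	-	+	+
kefB	-	-	-	-	+	+	-	+
pCM410	+	+	+	+	+	+	+	+
pntAB	-	-	+	+	-	-	-	-
rpoA	+	-	-	-	-	-	-	+
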