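# Curated ACMG/AMP evidence for the 12 extended splice region variants
# (11 allele-level units: one confirmed-cis pair is analyzed jointly).
# rna_code: minigene-derived RNA evidence with its strength.
# pm1/pm2/pm3/pp4: "+" applied, "NA" not applied. comp: computational code
# presented for the unit (PP3 or BP4); whether PP3 counts is decided by the
# gating rule, not by this file. expected_tier: published classification,
# used only by tests/acceptance as the comparison value.
unit	rna_code	pm1	pm2	pm3	comp	pp4	expected_tier
c.6558+4A>G	PVS1_RNA:Strong	NA	+	+	PP3	+	LP
c.6052-51_6052-11del	PVS1_RNA:Strong	NA	+	+	PP3	+	LP
c.593-8C>G;c.1201-8C>G	PVS1_RNA:Moderate	NA	+	+	PP3	+	LP
c.6558+5G>C	PVS1_RNA:Strong	NA	+	+	PP3	+	LP
c.592+33_593-31del	PVS1_RNA:Strong	NA	+	NA	PP3	+	LP
c.1200G>A	PVS1_RNA:Strong	+	+	NA	PP3	NA	LP
c.1553A>G	PVS1_RNA:Strong	NA	+	NA	PP3	NA	LP
c.1798-3C>G	PVS1_RNA:Strong	+	+	NA	PP3	+	LP
c.3375+34G>A	BP7_RNA:Strong	NA	+	NA	BP4	NA	VUS
c.5043+3A>G	PVS1_RNA:Supporting	NA	+	NA	PP3	+	VUS
c.3630+45C>T	BP7_RNA:Strong	NA	+	NA	BP4	NA	VUS
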