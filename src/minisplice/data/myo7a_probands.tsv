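# Curated proband series: 11 probands carrying MYO7A extended splice region
# variants, with allele frequencies, database annotations, phase assertions
# and assay-panel membership. HGVS against the packaged NM_000260.4-like model.
# db: semicolon-separated source:class pairs, "-" if unannotated.
# phase_group: variants sharing a label are confirmed in cis. panel: main =
# assayed in the primary minigene panel, supp = supplementary panel, "-" =
# second allele (not an extended-region candidate).
proband_id	phenotype	hgvs	maf	db	phase_group	depth	gq	panel
HL-01	USH1B	c.6558+4A>G	0.0001	-	-	42	99	main
HL-01	USH1B	c.5552T>C	0.0002	ClinVar:P;DVD:P	-	38	99	-
HL-02	USH1B	c.6052-51_6052-11del	0.0000	-	-	35	99	main
HL-02	USH1B	c.1642C>T	0.0003	ClinVar:P	-	44	99	-
HL-03	USH1B	c.593-8C>G	0.0002	-	cis1	40	99	main
HL-03	USH1B	c.1201-8C>G	0.0002	-	cis1	41	99	main
HL-03	USH1B	c.5856+1G>A	0.0001	ClinVar:P;DVD:P	-	39	99	-
HL-04	DFNB2	c.6558+5G>C	0.0001	-	-	37	99	main
HL-04	DFNB2	c.6051+1G>A	0.0002	DVD:P	-	45	99	-
HL-05	DFNB2	c.592+33_593-31del	0.0000	-	-	33	99	main
HL-05	DFNB2	c.6028G>A	0.0010	DVD:P	-	47	99	-
HL-06	HL_unknown	c.1200G>A	0.0001	-	-	36	99	main
HL-06	HL_unknown	c.6027del	0.0001	ClinVar:P	-	43	99	-
HL-07	HL_unknown	c.1553A>G	0.0001	-	-	34	99	main
HL-07	HL_unknown	c.3696_3706del	0.0000	ClinVar:P	-	46	99	-
HL-07	HL_unknown	c.6182G>A	0.0004	DVD:LP	-	40	99	-
HL-08	DFNA11	c.1798-3C>G	0.0001	-	-	39	99	main
HL-S1	HL_unknown	c.3375+34G>A	0.0005	-	-	41	99	supp
HL-S1	HL_unknown	c.2075_2079delinsGTA	0.0001	ClinVar:P	-	38	99	-
HL-S2	HL_unknown	c.5043+3A>G	0.0001	-	-	42	99	supp
HL-S3	HL_unknown	c.3630+45C>T	0.0002	-	-	37	99	supp
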