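# Splice predictor scores for the 12 extended splice region variants.
# SYNTHETIC stand-ins: the published record reports these scores only
# qualitatively (SpliceAI/Pangolin above or below 0.2; MaxEntScan Alt below
# 6.2; small intronic deletions not scoreable), except c.1201-8C>G whose
# SpliceAI delta of 0.23 under the extended 500-nt window is the published
# value. Values here are chosen to be consistent with those statements.
# Missing scores are encoded as NA, never as 0.
variant_id	spliceai_delta	spliceai_window_nt	pangolin	mes_ref	mes_alt	dbscsnv_ada	dbscsnv_rf
c.6558+4A>G	0.91	50	0.88	9.8	4.1	0.99	0.92
c.6052-51_6052-11del	0.76	50	0.81	NA	NA	NA	NA
c.593-8C>G	0.55	50	0.49	8.9	5.6	0.97	0.88
c.1201-8C>G	0.23	500	0.18	9.4	5.8	0.93	0.81
c.6558+5G>C	0.84	50	0.79	9.8	5.0	0.98	0.90
c.592+33_593-31del	0.71	50	0.77	NA	NA	NA	NA
c.1200G>A	0.62	50	0.58	10.1	5.9	0.96	0.85
c.1553A>G	0.47	50	0.41	8.3	5.2	0.90	0.78
c.1798-3C>G	0.69	50	0.66	9.0	4.8	0.95	0.83
c.3375+34G>A	0.02	50	0.01	7.9	7.8	0.02	0.05
c.5043+3A>G	0.58	50	0.52	8.8	6.0	0.88	0.74
c.3630+45C>T	0.03	50	0.02	8.4	8.3	0.01	0.03
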