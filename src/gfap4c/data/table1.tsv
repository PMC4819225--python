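accession	symbol	copies_NPC	copies_LIFplus	copies_LIFminus	fold_LIFplus_NPC	fold_LIFminus_NPC	stat3_site	distance_bin
NM_011019	Osmr	0.20	14.43	0.27	72.14	1.33	○	10–30 kb from TES
NM_008760	Ogn	0.10	3.46	0.04	34.58	0.42	○	10–30 kb from TSS
NM_011313	S100a6	1.20	29.50	1.27	24.58	1.06	○	10–30 kb from TES
NM_172471	Itih5	0.60	11.04	1.81	18.40	3.02	○	>30 kb from TES
NM_175459	Glis3	0.40	2.97	0.38	7.43	0.94	○	>30 kb from TSS
NM_008046	Fst	0.20	1.36	0.23	6.82	1.16	○	>30 kb from TES
NM_133832	Rdh10	1.20	4.97	1.76	4.14	1.47	○	5–10 kb from TSS
NM_024283	Ecrg4	0.50	1.76	0.08	3.52	0.16	○	>30 kb from TSS
NM_011883	Rnf13	2.70	9.12	5.38	3.38	1.99	○	10–30 kb from TES
NM_175628	A2m	11.10	37.32	4.31	3.36	0.39	○	5–10 kb from TES
BC019423	Rsph9	0.80	1.99	0.61	2.48	0.76	×	10–30 kb from TES
BC110634	Galntl1	3.00	7.42	3.95	2.47	1.32	○	>30 kb from TES
NM_009011	Rad23b	6.00	14.72	11.27	2.45	1.88	×	>30 kb from TES
NM_009371	Tgfbr2	1.00	2.33	0.29	2.33	0.29	○	>30 kb from TSS
NM_173876	Clcn3	3.30	7.38	6.31	2.24	1.91	○	<2 kb from TES
NM_175836	Spnb2	4.60	10.06	6.84	2.19	1.49	○	>30 kb from TSS
NM_008654	Ppp1r15a	1.00	2.14	1.34	2.14	1.34	×	>30 kb from TES
BC094659	Gab1	11.70	23.66	11.72	2.02	1.00	×	2–5 kb from TES
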