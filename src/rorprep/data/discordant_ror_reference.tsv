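sample_id	subtype	prosigna_ror	prosigna_category	ror_macro	category_macro	ror_bulk	category_bulk
BC-34	LumA	39	low	37.87	low	63.56	high
BC-30	LumA	32	low	24.9	low	47.3	intermediate
BC-35	LumA	57	intermediate	54.86	intermediate	75.53	high
BC-20	LumA	39	low	34.69	low	53.77	intermediate
BC-85	LumA	30	low	25.65	low	42.83	intermediate
BC-72	LumA	41	intermediate	34.1	low	45.41	intermediate
BC-17	LumA	47	intermediate	39.94	low	49.07	intermediate
BC-88	LumB	57	intermediate	53.93	intermediate	60.06	high
BC-23	LumA	45	intermediate	42.71	intermediate	38.43	low
BC-58	LumA	46	intermediate	50.42	intermediate	28.99	low
BC-47	LumB	60	intermediate	56.66	intermediate	26.85	low
BC-38	LumB	55	intermediate	52.69	intermediate	16.35	low
BC-70	LumB	64	high	62.18	high	18.12	low
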