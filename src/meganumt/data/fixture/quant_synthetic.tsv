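# Synthetic replicate-level reconstruction of the rho0-cell
# quantification: raw replicate data are not public, so these
# mt:autosomal ratios are deterministic values affine-scaled such that
# copies (= 2 x ratio) have sample mean +/- SD exactly 45.00 +/- 5.27
# (ddPCR, n=20) and 56.16 +/- 4.35 (qPCR, n=76).
sample_id	method	target	replicate	value_type	value	dilution
III.4_rho0	ddpcr	ND1	0	mt_autosomal_ratio	23.933570	1
III.4_rho0	ddpcr	ND1	1	mt_autosomal_ratio	20.768804	1
III.4_rho0	ddpcr	ND1	2	mt_autosomal_ratio	19.646459	1
III.4_rho0	ddpcr	ND1	3	mt_autosomal_ratio	17.092946	1
III.4_rho0	ddpcr	ND1	4	mt_autosomal_ratio	21.952038	1
III.4_rho0	ddpcr	KAV	5	mt_autosomal_ratio	24.976693	1
III.4_rho0	ddpcr	KAV	6	mt_autosomal_ratio	22.681930	1
III.4_rho0	ddpcr	KAV	7	mt_autosomal_ratio	23.586530	1
III.4_rho0	ddpcr	KAV	8	mt_autosomal_ratio	24.552768	1
III.4_rho0	ddpcr	KAV	9	mt_autosomal_ratio	20.952698	1
III.4_rho0	ddpcr	BATZ	10	mt_autosomal_ratio	27.630724	1
III.4_rho0	ddpcr	BATZ	11	mt_autosomal_ratio	20.962594	1
III.4_rho0	ddpcr	BATZ	12	mt_autosomal_ratio	23.325240	1
III.4_rho0	ddpcr	BATZ	13	mt_autosomal_ratio	27.795659	1
III.4_rho0	ddpcr	BATZ	14	mt_autosomal_ratio	22.403571	1
III.4_rho0	ddpcr	AND	15	mt_autosomal_ratio	22.835392	1
III.4_rho0	ddpcr	AND	16	mt_autosomal_ratio	21.652287	1
III.4_rho0	ddpcr	AND	17	mt_autosomal_ratio	23.251503	1
III.4_rho0	ddpcr	AND	18	mt_autosomal_ratio	18.601244	1
III.4_rho0	ddpcr	AND	19	mt_autosomal_ratio	21.397349	1
III.4_rho0	qpcr	ND1	0	mt_autosomal_ratio	27.315897	1
III.4_rho0	qpcr	ND1	1	mt_autosomal_ratio	28.870189	1
III.4_rho0	qpcr	ND1	2	mt_autosomal_ratio	29.679414	1
III.4_rho0	qpcr	ND1	3	mt_autosomal_ratio	25.955787	1
III.4_rho0	qpcr	ND1	4	mt_autosomal_ratio	30.057924	1
III.4_rho0	qpcr	ND1	5	mt_autosomal_ratio	28.849307	1
III.4_rho0	qpcr	ND1	6	mt_autosomal_ratio	30.094035	1
III.4_rho0	qpcr	ND1	7	mt_autosomal_ratio	28.890238	1
III.4_rho0	qpcr	ND1	8	mt_autosomal_ratio	30.987703	1
III.4_rho0	qpcr	ND1	9	mt_autosomal_ratio	26.036903	1
III.4_rho0	qpcr	ND1	10	mt_autosomal_ratio	32.435601	1
III.4_rho0	qpcr	ND1	11	mt_autosomal_ratio	31.082915	1
III.4_rho0	qpcr	ND1	12	mt_autosomal_ratio	26.833360	1
III.4_rho0	qpcr	ND1	13	mt_autosomal_ratio	29.804466	1
III.4_rho0	qpcr	ND1	14	mt_autosomal_ratio	29.296601	1
III.4_rho0	qpcr	ND1	15	mt_autosomal_ratio	24.131793	1
III.4_rho0	qpcr	ND1	16	mt_autosomal_ratio	29.651328	1
III.4_rho0	qpcr	ND1	17	mt_autosomal_ratio	26.867687	1
III.4_rho0	qpcr	ND1	18	mt_autosomal_ratio	27.658455	1
III.4_rho0	qpcr	ND1	19	mt_autosomal_ratio	26.827634	1
III.4_rho0	qpcr	ND1	20	mt_autosomal_ratio	27.238602	1
III.4_rho0	qpcr	ND1	21	mt_autosomal_ratio	28.417069	1
III.4_rho0	qpcr	ND1	22	mt_autosomal_ratio	28.475977	1
III.4_rho0	qpcr	ND1	23	mt_autosomal_ratio	24.571784	1
III.4_rho0	qpcr	ND1	24	mt_autosomal_ratio	27.614382	1
III.4_rho0	qpcr	ND1	25	mt_autosomal_ratio	25.077154	1
III.4_rho0	qpcr	ND1	26	mt_autosomal_ratio	25.251708	1
III.4_rho0	qpcr	ND1	27	mt_autosomal_ratio	27.429891	1
III.4_rho0	qpcr	ND1	28	mt_autosomal_ratio	30.264551	1
III.4_rho0	qpcr	ND1	29	mt_autosomal_ratio	29.735360	1
III.4_rho0	qpcr	ND1	30	mt_autosomal_ratio	26.822278	1
III.4_rho0	qpcr	ND1	31	mt_autosomal_ratio	26.572912	1
III.4_rho0	qpcr	ND1	32	mt_autosomal_ratio	26.297076	1
III.4_rho0	qpcr	ND1	33	mt_autosomal_ratio	28.584485	1
III.4_rho0	qpcr	ND1	34	mt_autosomal_ratio	30.456356	1
III.4_rho0	qpcr	ND1	35	mt_autosomal_ratio	28.290492	1
III.4_rho0	qpcr	ND1	36	mt_autosomal_ratio	29.881331	1
III.4_rho0	qpcr	ND1	37	mt_autosomal_ratio	28.991602	1
III.4_rho0	qpcr	AND	38	mt_autosomal_ratio	31.794485	1
III.4_rho0	qpcr	AND	39	mt_autosomal_ratio	23.516582	1
III.4_rho0	qpcr	AND	40	mt_autosomal_ratio	23.223406	1
III.4_rho0	qpcr	AND	41	mt_autosomal_ratio	27.780055	1
III.4_rho0	qpcr	AND	42	mt_autosomal_ratio	29.748759	1
III.4_rho0	qpcr	AND	43	mt_autosomal_ratio	27.279945	1
III.4_rho0	qpcr	AND	44	mt_autosomal_ratio	29.251835	1
III.4_rho0	qpcr	AND	45	mt_autosomal_ratio	25.480963	1
III.4_rho0	qpcr	AND	46	mt_autosomal_ratio	25.278575	1
III.4_rho0	qpcr	AND	47	mt_autosomal_ratio	26.558399	1
III.4_rho0	qpcr	AND	48	mt_autosomal_ratio	30.231595	1
III.4_rho0	qpcr	AND	49	mt_autosomal_ratio	29.889800	1
III.4_rho0	qpcr	AND	50	mt_autosomal_ratio	26.566235	1
III.4_rho0	qpcr	AND	51	mt_autosomal_ratio	28.674975	1
III.4_rho0	qpcr	AND	52	mt_autosomal_ratio	26.721099	1
III.4_rho0	qpcr	AND	53	mt_autosomal_ratio	28.295231	1
III.4_rho0	qpcr	AND	54	mt_autosomal_ratio	25.620659	1
III.4_rho0	qpcr	AND	55	mt_autosomal_ratio	28.138169	1
III.4_rho0	qpcr	AND	56	mt_autosomal_ratio	26.513182	1
III.4_rho0	qpcr	AND	57	mt_autosomal_ratio	28.143343	1
III.4_rho0	qpcr	AND	58	mt_autosomal_ratio	26.710555	1
III.4_rho0	qpcr	AND	59	mt_autosomal_ratio	26.310441	1
III.4_rho0	qpcr	AND	60	mt_autosomal_ratio	28.515381	1
III.4_rho0	qpcr	AND	61	mt_autosomal_ratio	27.451484	1
III.4_rho0	qpcr	AND	62	mt_autosomal_ratio	28.299030	1
III.4_rho0	qpcr	AND	63	mt_autosomal_ratio	27.259820	1
III.4_rho0	qpcr	AND	64	mt_autosomal_ratio	29.695010	1
III.4_rho0	qpcr	AND	65	mt_autosomal_ratio	26.324722	1
III.4_rho0	qpcr	AND	66	mt_autosomal_ratio	30.060486	1
III.4_rho0	qpcr	AND	67	mt_autosomal_ratio	31.388447	1
III.4_rho0	qpcr	AND	68	mt_autosomal_ratio	27.613953	1
III.4_rho0	qpcr	AND	69	mt_autosomal_ratio	32.362848	1
III.4_rho0	qpcr	AND	70	mt_autosomal_ratio	33.033533	1
III.4_rho0	qpcr	AND	71	mt_autosomal_ratio	29.292611	1
III.4_rho0	qpcr	AND	72	mt_autosomal_ratio	25.046988	1
III.4_rho0	qpcr	AND	73	mt_autosomal_ratio	24.438469	1
III.4_rho0	qpcr	AND	74	mt_autosomal_ratio	27.833485	1
III.4_rho0	qpcr	AND	75	mt_autosomal_ratio	32.435201	1
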