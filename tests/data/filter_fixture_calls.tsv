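sample_id	chrom	start	end	state	copy_number	n_probes	confidence	algorithm
BAD1	1	1000001	1200000	dup	3	4	30.0	iPattern
BAD2	1	2000001	2099000	del	1	12	30.0	iPattern
BAD3	1	3000001	3200000	dup	3	15	14.0	QuantiSNP
BAD4	2	5000001	5200000	del	1	20	30.0	PennCNV
BAD5	2	7000001	7150000	dup	3	20	30.0	iPattern
OK00	1	9000001	9150000	del	1	10	25.0	iPattern
OK01	2	9400001	9560000	dup	3	11	26.0	PennCNV
OK02	1	9800001	9970000	dup	3	12	27.0	QuantiSNP
OK03	2	10200001	10380000	del	1	13	28.0	iPattern
OK04	1	10600001	10790000	dup	3	14	29.0	PennCNV
OK05	2	11000001	11150000	dup	3	15	30.0	QuantiSNP
OK06	1	11400001	11560000	del	1	16	31.0	iPattern
OK07	2	11800001	11970000	dup	3	17	32.0	PennCNV
OK08	1	12200001	12380000	dup	3	18	33.0	QuantiSNP
OK09	2	12600001	12790000	del	1	19	34.0	iPattern
OK10	1	13000001	13150000	dup	3	20	35.0	PennCNV
OK11	2	13400001	13560000	dup	3	21	36.0	QuantiSNP
OK12	1	13800001	13970000	del	1	22	37.0	iPattern
OK13	2	14200001	14380000	dup	3	23	38.0	PennCNV
OK14	1	14600001	14790000	dup	3	24	39.0	QuantiSNP
OK15	2	15000001	15150000	del	1	25	40.0	iPattern
OK16	1	15400001	15560000	dup	3	26	41.0	PennCNV
OK17	2	15800001	15970000	dup	3	27	42.0	QuantiSNP
OK18	1	16200001	16380000	del	1	28	43.0	iPattern
OK19	2	16600001	16790000	dup	3	29	44.0	PennCNV
OK20	1	17000001	17150000	dup	3	30	45.0	QuantiSNP
OK21	2	17400001	17560000	del	1	31	46.0	iPattern
OK22	1	17800001	17970000	dup	3	32	47.0	PennCNV
OK23	2	18200001	18380000	dup	3	33	48.0	QuantiSNP
OK24	1	18600001	18790000	del	1	34	49.0	iPattern
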