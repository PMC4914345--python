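siRNA	cell_line	mean	sd
SOX11	BT20	51	8
SOX11	HCC1143	61	10
SOX11	MDA468	40	7
SOX11	MCF7	96	4
SOX11	T47D	72	3
SOX11	ZR751	95	10
ATF4	BT20	65	19
ATF4	HCC1143	49	17
ATF4	MDA468	47	2
ATF4	MCF7	70	7
ATF4	T47D	38	1
ATF4	ZR751	78	9
FOXM1	BT20	34	5
FOXM1	HCC1143	70	17
FOXM1	MDA468	52	6
FOXM1	MCF7	77	11
FOXM1	T47D	66	8
FOXM1	ZR751	105	21
FOSL2	BT20	52	11
FOSL2	HCC1143	53	12
FOSL2	MDA468	71	27
FOSL2	MCF7	93	21
FOSL2	T47D	60	35
FOSL2	ZR751	84	12
TFDP1	BT20	56	11
TFDP1	HCC1143	34	14
TFDP1	MDA468	103	16
TFDP1	MCF7	45	8
TFDP1	T47D	119	89
TFDP1	ZR751	123	14
MYC	BT20	40	5
MYC	HCC1143	34	6
MYC	MDA468	71	11
MYC	MCF7	76	15
MYC	T47D	42	3
MYC	ZR751	59	14
CDC5L	BT20	36	5
CDC5L	HCC1143	25	13
CDC5L	MDA468	25	9
CDC5L	MCF7	68	2
CDC5L	T47D	30	3
CDC5L	ZR751	34	6
NFKB2	BT20	41	7
NFKB2	HCC1143	23	7
NFKB2	MDA468	4	4
NFKB2	MCF7	14	1
NFKB2	T47D	28	2
NFKB2	ZR751	91	14
E2F2	BT20	44	11
E2F2	HCC1143	68	12
E2F2	MDA468	79	16
E2F2	MCF7	55	15
E2F2	T47D	62	46
E2F2	ZR751	77	9
KLF5	BT20	74	3
KLF5	HCC1143	71	7
KLF5	MDA468	55	5
KLF5	MCF7	57	16
KLF5	T47D	79	11
KLF5	ZR751	109	8
RXRB	BT20	36	5
RXRB	HCC1143	70	8
RXRB	MDA468	93	21
RXRB	MCF7	87	33
RXRB	T47D	28	4
RXRB	ZR751	68	9
SOX6	BT20	55	7
SOX6	HCC1143	70	10
SOX6	MDA468	89	9
SOX6	MCF7	100	5
SOX6	T47D	43	1
SOX6	ZR751	76	6
E2F5	BT20	66	17
E2F5	HCC1143	107	31
E2F5	MDA468	173	9
E2F5	MCF7	140	10
E2F5	T47D	49	3
E2F5	ZR751	120	10
NFYA	BT20	70	6
NFYA	HCC1143	74	11
NFYA	MDA468	65	6
NFYA	MCF7	83	29
NFYA	T47D	101	7
NFYA	ZR751	62	11
CEBPB	BT20	98	18
CEBPB	HCC1143	71	15
CEBPB	MDA468	56	8
CEBPB	MCF7	67	5
CEBPB	T47D	76	21
CEBPB	ZR751	38	12
CEBPG	BT20	70	4
CEBPG	HCC1143	86	19
CEBPG	MDA468	55	4
CEBPG	MCF7	103	5
CEBPG	T47D	96	9
CEBPG	ZR751	82	6
SOX4	BT20	76	17
SOX4	HCC1143	61	8
SOX4	MDA468	90	9
SOX4	MCF7	80	10
SOX4	T47D	71	11
SOX4	ZR751	91	5
KLF11	BT20	122	32
KLF11	HCC1143	60	13
KLF11	MDA468	88	14
KLF11	MCF7	88	9
KLF11	T47D	77	19
KLF11	ZR751	106	5
KLF13	BT20	65	7
KLF13	HCC1143	87	4
KLF13	MDA468	83	20
KLF13	MCF7	100	7
KLF13	T47D	81	10
KLF13	ZR751	90	7
NFYC	BT20	73	12
NFYC	HCC1143	72	7
NFYC	MDA468	78	8
NFYC	MCF7	105	13
NFYC	T47D	110	40
NFYC	ZR751	39	12
SOX9	BT20	91	15
SOX9	HCC1143	94	15
SOX9	MDA468	99	7
SOX9	MCF7	108	18
SOX9	T47D	66	10
SOX9	ZR751	64	7
SOX10	BT20	102	24
SOX10	HCC1143	81	16
SOX10	MDA468	132	9
SOX10	MCF7	154	16
SOX10	T47D	32	4
SOX10	ZR751	116	9
CREB5	BT20	84	15
CREB5	HCC1143	70	26
CREB5	MDA468	99	13
CREB5	MCF7	111	14
CREB5	T47D	33	1
CREB5	ZR751	117	6
PPARD	BT20	76	17
PPARD	HCC1143	67	9
PPARD	MDA468	118	13
PPARD	MCF7	88	22
PPARD	T47D	56	8
PPARD	ZR751	78	13
ARNT	BT20	131	36
ARNT	HCC1143	153	29
ARNT	MDA468	138	12
ARNT	MCF7	132	9
ARNT	T47D	22	2
ARNT	ZR751	105	12
STAT1	BT20	108	22
STAT1	HCC1143	113	7
STAT1	MDA468	80	14
STAT1	MCF7	83	6
STAT1	T47D	56	8
STAT1	ZR751	93	16
PPARA	BT20	103	12
PPARA	HCC1143	131	26
PPARA	MDA468	107	5
PPARA	MCF7	94	7
PPARA	T47D	97	10
PPARA	ZR751	81	7
KLF12	BT20	119	13
KLF12	HCC1143	79	2
KLF12	MDA468	91	2
KLF12	MCF7	96	10
KLF12	T47D	79	13
KLF12	ZR751	107	6
E2F3	BT20	76	5
E2F3	HCC1143	138	17
E2F3	MDA468	107	11
E2F3	MCF7	83	10
E2F3	T47D	85	11
E2F3	ZR751	91	27
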