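subclass	mol_id	nominal_mw	exp_abundance	pred_abundance	printed_diff
Pyrimidines	5	126	82	32	-50
Pyrimidines	16	140	64	98	+34
Pyrimidines	17	140	100	71	-29
Pyrimidines	19	141	100	91	-9
Pyrimidines	41	154	100	65	-35
Pyrimidines	42	154	80	57	-23
Pyrimidines	43	155	100	97	-3
Pyrimidines	81	170	100	41	-59
Xanthines	39	153	94	100	+6
Xanthines	75	168	27	100	+73
Xanthines	100	180	100	57	-43
Xanthines	106	181	25	67	+42
Xanthines	132	195	14	49	+35
Hypoxanthines	28	150	100	83	-17
Hypoxanthines	31	150	70	100	+30
Hypoxanthines	52	164	100	57	-43
Lumazines	65	166	2	100	+98
Lumazines	96	180	100	64	-36
Lumazines	121	192	100	79	-21
Lumazines	128	194	100	87	-13
Quinazolinediones	86	177	60	26	-34
Quinazolinediones	115	190	100	87	-13
Quinazolinediones	120	192	100	88	-12
Remycins	92	179	66	19	-47
Remycins	105	181	1	49	+48
Remycins	123	193	24	40	+16
Remycins	125	193	63	27	-36
Remycins	126	193	100	31	-69
Remycins	147	207	14	23	+9
Pyridopyrimidinediones	47	163	100	82	-18
Pyridopyrimidinediones	50	163	88	100	+12
Pyridopyrimidinediones	116	191	100	84	-16
Pyridopyrimidinediones	117	191	100	54	-46
Pyridopyrimidinediones	118	191	100	90	-10
Others	70	167	11	89	+78
Others	74	168	100	59	-41
Others	80	170	100	21	-79
Others	122	192	49	100	-51
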