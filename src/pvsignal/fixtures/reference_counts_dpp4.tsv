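group_name	n11	n1plus	ic	ic025	ic975	classification
dpp4_inhibitors	101	6898	-0.46	-0.75	-0.17	inverse
alogliptin	15	633	0.21	-0.52	0.94	none
anagliptin	2	212	-0.82	-2.5	0.85	none
linagliptin	8	736	-0.82	-1.79	0.14	none
omarigliptin	0	131				
saxagliptin	1	224	-1.47	-3.52	0.58	none
sitagliptin	26	2131	-0.71	-1.27	-0.15	inverse
teneligliptin	4	587	-1.37	-2.66	-0.07	inverse
trelagliptin	4	166	0.19	-1.12	1.5	none
vildagliptin	45	2183	0.02	-0.41	0.46	none
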