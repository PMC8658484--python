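stratum	ace_n11	ace_n1plus	ace_rr	dpp4_n11	dpp4_n1plus	dpp4_rr
Total	176	1578	11.2	101	6898	1.5
Female	60	661	9.1	44	2739	1.6
Male	116	917	12.6	57	4159	1.4
<40	5	173	2.9	1	83	1.2
40-49	3	60	5.0	7	269	2.6
50-59	19	163	11.7	21	645	3.3
60-69	48	333	14.4	22	1659	1.3
70-79	57	501	11.4	29	2342	1.2
80-89	43	299	14.4	18	1634	1.1
>=90	1	49	2.0	3	266	1.1
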