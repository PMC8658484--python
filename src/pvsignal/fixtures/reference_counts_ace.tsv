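group_name	n11	n1plus	ic	ic025	ic975	classification
ace_inhibitors	176	1578	2.42	2.19	2.65	signal
alacepril	3	21	1.47	-0.1	3.03	none
benazepril	1	13	0.64	-1.54	2.82	none
captopril	2	63	0.39	-1.32	2.09	none
cilazapril	1	12	0.66	-1.53	2.85	none
delapril	0	10	-0.29	-3.3	2.72	none
enalapril	86	771	2.39	2.06	2.71	signal
imidapril	48	291	2.83	2.38	3.27	signal
lisinopril	17	133	2.28	1.55	3.0	signal
perindopril	6	114	1.07	-0.05	2.2	none
quinapril	1	30	0.3	-1.81	2.4	none
temocapril	7	105	1.35	0.29	2.4	signal
trandolapril	4	33	1.57	0.19	2.95	signal
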