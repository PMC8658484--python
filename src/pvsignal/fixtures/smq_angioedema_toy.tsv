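pt_code	pt_name	smq_id	scope
PT_ANGIO_N1	Angioedema narrow term 1	20000024	narrow
PT_ANGIO_N2	Angioedema narrow term 2	20000024	narrow
PT_ANGIO_B1	Angioedema broad term 1	20000024	broad
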