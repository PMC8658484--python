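alacepril
benazepril
captopril
cilazapril
delapril
enalapril
imidapril
lisinopril
perindopril
quinapril
temocapril
trandolapril
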