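cpg_id	S1	S2
cg01	0.10	0.12
cg02	0.90	0.88
cg03	0.50	0.52
cg04	0.30	0.28
cg05	0.20	0.40
cg06	0.60	0.62
cg07	0.15	0.18
cg08	0.80	0.78
cg09	0.45	0.47
cg10	0.25	0.27
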