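rna	metazoa	protists_wide	protists_model	fungi_wide	fungi_model	metazoa_minor
U1	0.38	0.58	0.51	0.51	0.52
U2	0.29	0.44	0.42	0.49	0.43
U4	0.22	0.48	0.47	0.57	0.57
U5	0.37	0.46	0.42	0.43	0.45
U11						0.63
U12						0.58
U4atac						0.48
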