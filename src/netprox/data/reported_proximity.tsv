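mol_id	d_S	d_C	d_K	S_P
MOL17	2.68	2.09	5.11	-2.09
MOL01	2.59	1.87	4.99	-2.01
MOL33	2.53	2.09	4.94	-1.98
MOL02	2.81	2.19	5.33	-1.95
MOL16	2.58	2.14	5.01	-1.84
MOL10	2.60	2.15	5.03	-1.75
MOL12	2.88	2.22	5.42	-1.71
MOL07	2.40	2.03	4.79	-1.54
MOL29	2.42	1.94	4.78	-1.53
MOL36	2.48	2.21	4.91	-0.98
MOL08	2.59	2.25	5.03	-0.88
MOL23	2.87	2.24	5.44	-0.86
MOL19	2.16	2.04	4.52	-0.64
MOL03	2.64	2.22	5.11	-0.49
MOL34	2.64	2.22	5.11	-0.49
MOL35	2.64	2.22	5.11	-0.49
MOL06	2.48	1.93	4.82	-0.32
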