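# 5' splice-site (donor) position frequencies, positions -3..+6
# (-3..-1 exonic, +1..+6 intronic); consensus MAG|GTRAGT
pos	A	C	G	T
-3	0.33	0.37	0.18	0.12
-2	0.60	0.13	0.14	0.13
-1	0.09	0.03	0.80	0.08
1	0.01	0.01	0.97	0.01
2	0.02	0.02	0.08	0.88
3	0.60	0.03	0.34	0.03
4	0.70	0.08	0.12	0.10
5	0.06	0.06	0.82	0.06
6	0.16	0.17	0.19	0.48
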