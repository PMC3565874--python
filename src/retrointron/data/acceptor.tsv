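# 3' splice-site (acceptor) position frequencies, positions -20..+3
# (-20..-1 intronic ending in AG, +1..+3 exonic); consensus Y(n)NCAG|G
pos	A	C	G	T
-20	0.10	0.31	0.11	0.48
-19	0.10	0.31	0.11	0.48
-18	0.10	0.31	0.11	0.48
-17	0.10	0.31	0.11	0.48
-16	0.10	0.31	0.11	0.48
-15	0.10	0.31	0.11	0.48
-14	0.10	0.31	0.11	0.48
-13	0.10	0.31	0.11	0.48
-12	0.10	0.31	0.11	0.48
-11	0.10	0.31	0.11	0.48
-10	0.09	0.33	0.10	0.48
-9	0.09	0.33	0.10	0.48
-8	0.09	0.35	0.09	0.47
-7	0.08	0.36	0.08	0.48
-6	0.08	0.36	0.08	0.48
-5	0.07	0.36	0.07	0.50
-4	0.24	0.30	0.21	0.25
-3	0.04	0.64	0.01	0.31
-2	0.97	0.01	0.01	0.01
-1	0.01	0.01	0.97	0.01
1	0.25	0.14	0.47	0.14
2	0.25	0.25	0.25	0.25
3	0.25	0.25	0.25	0.25
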