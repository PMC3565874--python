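# branch-site 7-mer frequencies, consensus nyURAYn with the branch
# adenosine at position 5; searched -45..-15 upstream of the acceptor
pos	A	C	G	T
1	0.25	0.25	0.25	0.25
2	0.15	0.35	0.15	0.35
3	0.08	0.10	0.07	0.75
4	0.35	0.15	0.35	0.15
5	0.92	0.03	0.03	0.02
6	0.13	0.35	0.12	0.40
7	0.25	0.25	0.25	0.25
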