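# Positional nucleotide frequencies for the human 3' (acceptor) splice-site
# 23-mer, window positions 1-23 = intron -20..-1 | exon +1..+3, compiled from
# published genome-wide surveys of annotated human GT-AG acceptor sites
# (polypyrimidine tract, positions 1-18; obligate AG at positions 19-20;
# exonic positions 21-23).
# Synthetic in-package parameter set, reconstructed from published
# positional frequency summaries of annotated human splice sites.
position	A	C	G	T
1	0.22	0.27	0.18	0.33
2	0.21	0.27	0.17	0.35
3	0.20	0.28	0.16	0.36
4	0.19	0.28	0.15	0.38
5	0.18	0.29	0.14	0.39
6	0.17	0.30	0.13	0.40
7	0.16	0.30	0.12	0.42
8	0.15	0.31	0.11	0.43
9	0.14	0.31	0.11	0.44
10	0.13	0.32	0.10	0.45
11	0.12	0.32	0.10	0.46
12	0.11	0.33	0.09	0.47
13	0.10	0.34	0.08	0.48
14	0.09	0.35	0.07	0.49
15	0.08	0.36	0.06	0.50
16	0.08	0.37	0.06	0.49
17	0.24	0.30	0.21	0.25
18	0.03	0.64	0.01	0.32
19	0.9937	0.0021	0.0022	0.0020
20	0.0026	0.0025	0.9924	0.0025
21	0.25	0.14	0.49	0.12
22	0.27	0.22	0.23	0.28
23	0.24	0.26	0.24	0.26
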