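# Positional nucleotide frequencies for the human 5' (donor) splice-site 9-mer,
# window positions 1-9 = exon -3..-1 | intron +1..+6, compiled from published
# genome-wide surveys of annotated human GT-AG donor sites. Positions 4-5 hold
# the obligate-dinucleotide consensus frequencies (canonical G, T).
# Synthetic in-package parameter set, reconstructed from published
# positional frequency summaries of annotated human splice sites.
position	A	C	G	T
1	0.33	0.37	0.18	0.12
2	0.60	0.13	0.12	0.15
3	0.08	0.04	0.81	0.07
4	0.0034	0.0032	0.9903	0.0031
5	0.0037	0.0040	0.0039	0.9884
6	0.58	0.04	0.35	0.03
7	0.71	0.09	0.12	0.08
8	0.07	0.06	0.82	0.05
9	0.16	0.17	0.20	0.47
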