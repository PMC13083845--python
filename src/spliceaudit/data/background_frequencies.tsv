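# Background (null) nucleotide frequencies used in the log2-odds denominator,
# the intronic background composition conventionally used for human splice-site
# models.
base	frequency
A	0.27
C	0.23
G	0.23
T	0.27
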