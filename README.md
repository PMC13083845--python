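# spliceaudit

Cryptic splice sites hide in plain sight in everyday molecular-biology
reagents: codon-optimized transgenes, epitope tags (V5, HA), Gly-Ser linkers,
and multiple-cloning sites can all, by accident of nucleotide choice, encode
functional 5′ (donor) or 3′ (acceptor) splice signals. When they do, the
mature transcript is not the one on the plasmid map — tags get spliced out,
chimeric mRNAs appear, and experiments quietly report artifacts.

`spliceaudit` is a toolkit for auditing and fixing transgene constructs
before (and after) they go into cells:

* **score** candidate splice windows with a maximum-entropy model of human
  splice sites — donor sites as 9-mers (3 exonic + GT + 4 intronic bases),
  acceptor sites as 23-mers (18-base tract + AG + 3 exonic bases);
* **scan** whole plasmids (circular topology supported, both strands) for
  windows above threshold plus hazard motifs (KpnI `GGTACC`, NheI `GCTAGC`,
  polyadenylation hexamers);
* **profile** the synonymous codon space of a peptide tag or linker —
  exhaustively or by uniform sampling — for the fraction of encodings that
  are splicing-prone;
* **design** splice-safe encodings by silent mutation (seeded stochastic
  search with independent re-verification);
* **quantify** aberrant splicing from RNA-seq mapped to the *entire* plasmid:
  junction counting from SAM `N` gaps and the per-junction spliced fraction
  `J/(J+I)`;
* **simulate** reads from a split-reporter plasmid with a known spliced
  fraction, for end-to-end validation without an external aligner.

## The score

A window `w` is scored in bits as

```
MaxEnt-style score(w) = log2( P_site(w) / P_background(w) )
```

where `P_site` is the maximum-entropy distribution consistent with positional
nucleotide frequencies of annotated human splice sites (which factorizes into
per-position odds, with the obligate GT/AG contributing a consensus-odds
term) and `P_background` uses the intronic background composition
(A/T 0.27, C/G 0.23). Scores ≥ 0 bits are treated as putative splice sites —
the conventional operating threshold. The parameter tables are packaged
plain-text fixtures with recorded checksums; see `docs/methods.md` for their
provenance and the model's scope.

## Worked example

Profile the common V5 tag, then design a splice-safe encoding:

```
$ spliceaudit tag-risk --preset V5 --n 100000 --seed 1
# tool=spliceaudit 0.1.0
# model_checksum=517f1dab4055
field   value
peptide GKPIPNPLLGLDST
n_evaluated     100000
mode    sampled
seed    1
tau     0.0
flank_policy    internal_only
prone5_fraction 0.200630
prone3_fraction 0.629950
prone_both_fraction     0.124640
```

So 20% of uniformly sampled V5 encodings contain an internal donor window
scoring ≥ 0 bits, 63% an internal acceptor window, and 12.5% both — picking a
V5 encoding at random is a gamble. The designer removes the risk:

```
$ spliceaudit optimize --preset V5 --seed 1
# tool=spliceaudit 0.1.0
# model_checksum=517f1dab4055
field   value
peptide GKPIPNPLLGLDST
encoding        GGCAAGCCTATTCCAAACCCTTTGCTCGGCTTGGACTCAACT
max_donor       NA
max_acceptor    NA
tau     0.0
flank_policy    internal_only
iterations      2
restarts        0
seed    1
```

The returned encoding still translates to GKPIPNPLLGLDST but hosts no
canonical donor or acceptor window at all (`NA` maxima); the result is
re-verified by an independent scan before it is returned. Other subcommands: `scan` (plasmid audit → TSV/BED),
`ambiguous` (IUPAC patterns such as `NNGGTACCN`), `linker-curve`
(splicing-prone fraction of (GGGGS)ₖ linkers vs length), `simulate` and
`junctions` (reporter simulation and RNA-seq junction quantification).

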