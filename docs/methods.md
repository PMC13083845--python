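# Methods

## Splice-site model

Candidate splice sites are scored as fixed-geometry windows. A donor (5′
splice site) window is a 9-mer spanning the exon|intron boundary: 3 exonic
bases, the obligate GT dinucleotide at window positions 4–5, and 4 further
intronic bases. An acceptor (3′ splice site) window is a 23-mer spanning the
intron|exon boundary: an 18-base stretch covering the polypyrimidine tract,
the obligate AG at positions 19–20, and 3 exonic bases. These geometries are
single constants shared by every module.

The score of a window `w` is the log2-odds of `w` under a model of authentic
human splice sites versus a background model,
`score(w) = log2(P_site(w) / P_background(w))`, in bits. `P_site` is the
maximum-entropy distribution subject to positional (first-order) nucleotide
frequency constraints. Under first-order constraints the maximum-entropy
solution factorizes across positions, so the score reduces to a sum of
per-position log-odds; the obligate GT/AG positions carry consensus
frequencies close to 1, contributing ≈ +4 bits when present and a penalty of
roughly −12 bits when absent — which is why non-canonical windows are
scoreable but never called. The positional frequencies are compiled from
published genome-wide surveys of annotated human GT–AG introns
(Shapiro–Senapathy-style donor/acceptor profiles and polypyrimidine-tract
composition); the background is the conventional intronic composition
A/T = 0.27, C/G = 0.23. The tables ship as plain-text fixtures under
`spliceaudit/data/`; they are an in-package synthetic reconstruction
parameterized from published summary frequencies, not a copy of any external
tool's distribution files. Their sha256 checksums are verified on load and a
combined 12-hex model checksum is stamped into every report, so results are
traceable to an exact parameter set.

Because the model is first-order, it omits the between-position dependencies
(e.g. the compensation between the exonic −1 G and intronic +5 G of donor
sites) that richer published models capture. Consequences observed with this
model: scores for GT-rich but off-consensus windows (such as
Gly-Gly-Ser-derived `GAGGTAGTN`) run ~1 bit lower than dependency-aware
models report, and score distributions over degenerate patterns are slightly
narrower. The threshold convention is unchanged: ≥ 0 bits marks a putative
site, and that is the default `tau` everywhere. Scores are computed in double
precision; reports print 2 decimals.

## Scanning

The scanner enumerates every window position on the requested strands,
keeping (by default) only canonical windows — GT/AG at the obligate
positions — with score ≥ `tau`. Coordinates are 0-based half-open on the
forward strand; reverse-strand windows report the forward interval they
occupy with `strand='-'`. Circular sequences (plasmids) are scanned as
`s + s[:W−1]` with starts reduced modulo L, so origin-spanning windows are
real hits and are reported with `end = start + W > L`. Windows containing N
are skipped and tallied in report metadata rather than expanded; explicit
degenerate patterns go through the IUPAC summarizer, which exhaustively
expands a pattern (cap 65,536 combinations), scores every literal window,
and reports min/max and the fraction ≥ `tau`. Hazard motifs flagged by
default: KpnI `GGTACC` and NheI `GCTAGC` (restriction sites documented to
act as splice signals in transcripts) and the polyadenylation hexamers
`AATAAA`/`ATTAAA`. The scanner's vectorized path is continuously checked in
the test suite against a naive per-position scorer and an independent
linear-space probability-product route.

## Codon-space risk profiles

For a peptide of length L, the synonymous encoding space is the product of
per-residue codon degeneracies (standard genetic code, no stop codons).
Spaces ≤ 10⁶ can be enumerated exhaustively in lexicographic codon order;
larger spaces are profiled by Monte-Carlo sampling with each residue's codon
drawn independently and uniformly. Uniform (not usage-weighted) draws are the
default because the question is a property of the encoding space itself;
duplicates are retained so fractions are unbiased estimates under that
measure. An encoding is *splicing-prone* for a kind when its maximum
canonical window score reaches `tau` (default 0 bits).

Which windows an encoding can host is governed by the flank policy:

* `internal_only` (default): only windows fully inside the encoding. Note
  the hard combinatorial ceiling this imposes on short tags: a 42-nt V5
  encoding can host an internal donor window only if a GT falls at least 3 nt
  from the 5′ end and 4 nt from the 3′ end, which happens in only ~46% of
  uniformly sampled encodings (and an internal 23-mer acceptor window fits in
  ~70%), bounding the both-prone fraction at ~46% regardless of the scoring
  model.
* `expand_N`: the obligate GT/AG must be inside the encoding, but the window
  may extend into unknown context scored worst-case (each outside position
  contributes its maximum log-odds). This is the recommended policy for
  building blocks destined for arbitrary vector contexts.
* `fixed_flanks`: the encoding is scored inside caller-supplied left/right
  context; windows count when their obligate dinucleotide overlaps the
  encoding.

The linker curve repeats this profile for (unit)×k at increasing k (seeded
per length), exposing how GT-rich Gly/Ser codons make longer linkers
increasingly likely to harbor donor sites.

## Splice-safe design

The designer searches the synonymous space for an encoding whose every
canonical window scores below `tau`, optionally excluding forbidden motifs
and enforcing GC bounds. Search is seeded stochastic hill-climbing: from a
random encoding, all single-codon replacements at the residues overlapped by
the current worst-scoring window (or a violated constraint) are tried and the
best strictly-improving move is taken; at a local minimum the search restarts
from a fresh random encoding, up to `max_restarts`. Exact dynamic programming
was deliberately not used: acceptor windows span up to 9 codons, which makes
the DP state space large, while in practice tags and linkers are solved in a
handful of iterations — and soundness never depends on the search path,
because every returned encoding is re-verified by an independent
window-enumeration route before it is handed back. Infeasibility (budget
exhausted) raises an explicit error carrying the best encoding found; it is
never silently approximated. Verification treats only the transcribed
(forward) strand as splice-relevant, since splicing acts on the mRNA.

## Junction quantification

Spliced alignments (SAM, produced by any spliced aligner against the full
plasmid including backbone) are reduced to reference blocks: M/=/X advance
both read and reference, D advances the reference without splitting a block,
N closes a block and opens a junction gap, I/S/H advance only the read.
Unmapped, secondary, and supplementary records are dropped. A gap counts for
its junction — keyed by exact (donor_end, acceptor_start); no fuzzy merging,
since plasmid-scale alignment is unambiguous and merging would blur distinct
cryptic sites — when both flanking blocks are ≥ `min_anchor` (default 6)
bases. The per-junction spliced fraction is `J/(J+I)`: `J` junction-spanning
reads, `I` reads with ≥ `min_anchor` aligned bases strictly inside the intron
and no gap equal to the junction, so each read contributes to at most one
side. The "reads within the intron" denominator is operationalized as a read
count with the same anchor rule as `J` (not a coverage average); the
parameter is recorded in report metadata. `J+I = 0` yields a missing value,
not a crash. Duplicate reads are not collapsed.

## Read simulator

The simulator is a software stand-in for a split-reporter splicing assay: a
synthetic circular plasmid (`make_reporter`) carries a reporter ORF split by
an intron with a consensus-like donor, a polypyrimidine tract, and an
acceptor, with an optional test insert inside the intron. Each read derives
from the spliced transcript with probability `psi`, else the unspliced one;
starts are uniform; reads are error-free by default (an optional uniform
substitution rate exists for robustness checks). Reads are emitted as FASTQ
plus a SAM with exact CIGARs (`M-N-M` across the junction), so the junction
module can be tested end to end with no external aligner and exact truth.
With `span_junction` enabled, spliced reads are placed to cross the junction
and unspliced reads to overlap the intron interior (both satisfying the
anchor rule), making the junction-spanning count Binomial(n, psi) and the
spliced-fraction statistic a direct estimator of `psi`. Default validation
sizes — 5,000 reads of 100 nt on a ~1.3-kb reporter, psi ∈ {0, 0.05, 0.2,
0.5, 1} — give 3-binomial-SE recovery margins of about ±2 percentage points.

What the simulator does *not* emulate: sequencing error profiles, alignment
ambiguity and soft-clipping at junctions, fragment-length/paired-end
structure, expression mixtures of more than two isoforms, or multiple
competing junctions. Passing round-trip tests therefore validates the
counting and the statistic, not an aligner's behavior on real reads.

## Numerical and interface conventions

Scores use double precision throughout; reports round to 2 decimals.
Coordinates are 0-based half-open, BED-compatible. All stochastic entry
points require explicit seeds (numpy `default_rng`) and identical inputs
give byte-identical reports. TSV reports carry `#`-prefixed metadata lines
with tool version, parameters, seed, and model checksum; scanner output is
also exportable as BED6 with scores clamped to [0, 1000]. Degenerate inputs
are defined, not exceptional: sequences shorter than a window yield empty
scans; encodings too short to host a window count as not prone; an empty
junction denominator reports a missing value.

## Known limitations

The first-order maximum-entropy model is deliberately simple and
conservative in ways documented above; it does not model branch points,
splicing efficiency, or context beyond the window, and no deep-learning
predictor is included. The tag-risk default (`internal_only`) understates
risk for tags whose windows straddle the insertion boundary — use `expand_N`
for context-free worst-case screening. Promoter-strength prediction is out
of scope; cryptic-promoter and polyA hazards are covered only by motif
flagging.
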