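"""Synthetic RNA-seq reads from a split-reporter plasmid with a known intron.

This emulates, in software, a splicing-reporter experiment: a reporter ORF is
interrupted by an intron that is spliced out in a known fraction ``psi`` of
transcripts. Each simulated read derives from the spliced transcript (intron
removed) with probability ``psi``, otherwise from the unspliced transcript;
start positions are uniform over valid positions; reads are error-free by
default. Reads are emitted as FASTQ plus a matching SAM with exact CIGARs
(spliced reads crossing the junction get M-N-M), so downstream junction
quantification needs no external aligner and the simulation truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .errors import SpliceAuditError
from .seqio import NucSequence, write_tsv

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulation run."""

    name: str
    sequence: str
    intron_start: int
    intron_end: int
    psi: float
    n_reads: int
    read_length: int
    seed: int
    error_rate: float = 0.0

    def __post_init__(self):
        L = len(self.sequence)
        if not 0.0 <= self.psi <= 1.0:
            raise SpliceAuditError(f"psi must be in [0, 1], got {self.psi}")
        if not 0 <= self.intron_start < self.intron_end <= L:
            raise SpliceAuditError("intron interval outside the reference")
        spliced_len = L - (self.intron_end - self.intron_start)
        if self.read_length > spliced_len:
            raise SpliceAuditError(
                f"read_length {self.read_length} exceeds spliced transcript "
                f"length {spliced_len}")
        if self.n_reads < 1:
            raise SpliceAuditError("n_reads must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise SpliceAuditError("error_rate must be in [0, 1)")

    def truth_rows(self):
        for k in ("name", "intron_start", "intron_end", "psi", "n_reads",
                  "read_length", "seed", "error_rate"):
            yield (k, getattr(self, k))


@dataclass(frozen=True)
class SimRead:
    name: str
    sequence: str
    pos: int  # 0-based reference start
    cigar: str
    spliced: bool


def _spliced_read(ref: str, i0: int, i1: int, s: int, L: int):
    """Sequence/pos/cigar for a read at spliced-transcript coordinate s."""
    if s + L <= i0:
        return ref[s : s + L], s, f"{L}M", False
    if s >= i0:
        rs = s + (i1 - i0)
        return ref[rs : rs + L], rs, f"{L}M", False
    left = i0 - s
    right = L - left
    seq = ref[s:i0] + ref[i1 : i1 + right]
    return seq, s, f"{left}M{i1 - i0}N{right}M", True


def simulate_reads(
    truth: SimTruth,
    fastq_path=None,
    sam_path=None,
    truth_path=None,
    span_junction: bool = False,
    min_anchor: int = 6,
) -> list[SimRead]:
    """Simulate reads per ``truth``; optionally write FASTQ/SAM/truth TSV.

    With ``span_junction`` every spliced read is placed so that it crosses the
    junction with >= ``min_anchor`` bases on both sides, and every unspliced
    read overlaps the intron interior by >= ``min_anchor`` bases; the
    junction-spanning read count is then Binomial(n_reads, psi) and the
    spliced-fraction statistic estimates psi directly. Fully deterministic for
    a given seed (byte-identical FASTQ and SAM).
    """
    ref = truth.sequence
    i0, i1 = truth.intron_start, truth.intron_end
    L = truth.read_length
    rng = np.random.default_rng(truth.seed)
    spliced_len = len(ref) - (i1 - i0)

    if span_junction:
        # spliced-transcript starts with >= min_anchor on both junction sides
        sp_lo = max(0, i0 - (L - min_anchor))
        sp_hi = min(spliced_len - L, i0 - min_anchor)
        # unspliced starts overlapping the intron interior by >= min_anchor
        un_lo = max(0, i0 - L + min_anchor)
        un_hi = min(len(ref) - L, i1 - min_anchor)
        if sp_hi < sp_lo or un_hi < un_lo:
            raise SpliceAuditError(
                "read_length/min_anchor leave no junction-spanning starts")
    reads = []
    for k in range(truth.n_reads):
        is_spliced = bool(rng.random() < truth.psi)
        if is_spliced:
            lo, hi = (sp_lo, sp_hi) if span_junction else (0, spliced_len - L)
            s = int(rng.integers(lo, hi + 1))
            seq, pos, cigar, crosses = _spliced_read(ref, i0, i1, s, L)
        else:
            lo, hi = (un_lo, un_hi) if span_junction else (0, len(ref) - L)
            pos = int(rng.integers(lo, hi + 1))
            seq, cigar, crosses = ref[pos : pos + L], f"{L}M", False
        if truth.error_rate > 0.0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = rng.random(L) < truth.error_rate
            if hit.any():
                subs = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
                arr[hit] = subs
            seq = arr.tobytes().decode()
        reads.append(SimRead(f"read{k:06d}", seq, pos, cigar, crosses))

    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    if sam_path is not None:
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": truth.name, "LN": len(ref)}],
        }
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as af:
            for r in reads:
                rec = pysam.AlignedSegment(af.header)
                rec.query_name = r.name
                rec.query_sequence = r.sequence
                rec.flag = 0
                rec.reference_id = 0
                rec.reference_start = r.pos
                rec.mapping_quality = 60
                rec.cigarstring = r.cigar
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(r.sequence))
                af.write(rec)
    if truth_path is not None:
        write_tsv(truth_path, ("field", "value"), truth.truth_rows())
    return reads


def make_reporter(
    seed: int = 0,
    insert: str = "",
    exon_length: int = 300,
    intron_core: int = 120,
    backbone_length: int = 600,
) -> tuple[NucSequence, int, int]:
    """Build a synthetic circular reporter plasmid with one defined intron.

    The reporter ORF is split by an intron carrying a consensus-like donor,
    a pyrimidine tract and acceptor; ``insert`` (e.g. a tag encoding under
    audit) is placed inside the intron. Returns the plasmid plus the intron's
    [start, end) coordinates. Synthetic composition stand-in for a split-
    fluorophore splicing-reporter construct; not a curated vector sequence.
    """
    rng = np.random.default_rng(seed)

    def random_seq(n, p=(0.27, 0.23, 0.23, 0.27)):
        return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))

    exon1 = random_seq(exon_length - 3) + "CAG"  # consensus donor context
    donor = "GTAAGT"
    tract = "CTTTCTTTTCTCTTTTTCCTTTCAG"  # PPT + acceptor AG
    filler = random_seq(max(0, intron_core - len(donor) - len(tract)))
    intron = donor + filler + insert.upper().replace("U", "T") + tract
    exon2 = "G" + random_seq(exon_length - 1)
    backbone = random_seq(backbone_length)
    bases = exon1 + intron + exon2 + backbone
    intron_start = len(exon1)
    intron_end = intron_start + len(intron)
    plasmid = NucSequence(f"reporter_seed{seed}", bases, "circular")
    return plasmid, intron_start, intron_end
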