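"""Splice-junction quantification from spliced alignments to a plasmid.

Diagnostic RNA-seq for a transgene construct is mapped (by any spliced
aligner) against the *entire* plasmid sequence, backbone included; this module
consumes the resulting SAM, extracts N-gap junctions with an anchor rule, and
computes the per-junction spliced fraction

    spliced_fraction = J / (J + I)

where ``J`` counts reads spanning the junction (N gap exactly matching the
intron, >= ``min_anchor`` aligned bases on both sides) and ``I`` counts reads
with >= ``min_anchor`` aligned bases strictly inside the intron and no gap
equal to the junction. Junctions are keyed by exact coordinates; duplicate
reads are not collapsed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pysam

from .errors import AlignmentError
from .seqio import write_tsv

# CIGAR op codes (pysam numeric codes)
_M, _I, _D, _N, _S, _H, _P, _EQ, _X = 0, 1, 2, 3, 4, 5, 6, 7, 8
_ALLOWED_OPS = {_M, _I, _D, _N, _S, _H, _EQ, _X}
_REF_CONSUMING = {_M, _D, _EQ, _X}


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to its reference footprint.

    ``blocks`` are disjoint ascending 0-based half-open reference intervals of
    contiguous alignment (M/=/X, with D bridged); consecutive blocks are
    separated by N gaps, listed in ``gaps``.
    """

    name: str
    reference: str
    start: int
    cigar: tuple
    blocks: tuple
    gaps: tuple


@dataclass(frozen=True)
class Junction:
    """An observed splice junction: intron is [donor_end, acceptor_start)."""

    reference: str
    donor_end: int
    acceptor_start: int
    read_count: int

    def __post_init__(self):
        if not self.donor_end < self.acceptor_start:
            raise AlignmentError("junction donor_end must precede acceptor_start")
        if self.read_count < 1:
            raise AlignmentError("junction read_count must be >= 1")


@dataclass
class SpliceQuantReport:
    junctions: list
    spliced_fractions: list  # parallel to junctions; None = undefined
    min_anchor: int
    n_reads: int
    n_anchor_failed_gaps: int
    model_note: str = "junction keying: exact coordinates (tolerance 0)"

    def to_tsv(self, handle_or_path, metadata: dict | None = None) -> None:
        meta = {
            "min_anchor": self.min_anchor,
            "n_reads": self.n_reads,
            "n_gaps_failing_anchor": self.n_anchor_failed_gaps,
            "junction_keying": "exact",
        }
        meta.update(metadata or {})
        rows = [
            (j.reference, j.donor_end, j.acceptor_start, j.read_count,
             "NA" if f is None else f"{f:.6f}")
            for j, f in zip(self.junctions, self.spliced_fractions)
        ]
        write_tsv(handle_or_path,
                  ("ref", "donor_end", "acceptor_start", "count",
                   "spliced_fraction"),
                  rows, metadata=meta)


def _blocks_from_cigar(start: int, cigartuples) -> tuple[tuple, tuple]:
    blocks = []
    gaps = []
    ref = start
    block_start = start
    open_block = False
    for op, length in cigartuples:
        if op not in _ALLOWED_OPS:
            raise AlignmentError(f"unsupported CIGAR operation code {op}")
        if length <= 0:
            raise AlignmentError(f"non-positive CIGAR length {length}")
        if op in (_M, _EQ, _X):
            if not open_block:
                block_start = ref
                open_block = True
            ref += length
        elif op == _D:
            # deletion: reference consumed, block continues
            if not open_block:
                block_start = ref
                open_block = True
            ref += length
        elif op == _N:
            if open_block:
                blocks.append((block_start, ref))
                open_block = False
            gaps.append((ref, ref + length))
            ref += length
        # I, S, H consume no reference
    if open_block:
        blocks.append((block_start, ref))
    return tuple(blocks), tuple(gaps)


def read_alignments(sam_path) -> list[AlignedRead]:
    """Parse a SAM file into :class:`AlignedRead` records.

    Unmapped, secondary, and supplementary records are excluded. A missing
    header (no @SQ lines) and malformed CIGAR strings raise distinct
    :class:`AlignmentError` messages.
    """
    try:
        af = pysam.AlignmentFile(str(sam_path), "r", check_sq=True)
    except ValueError as exc:
        raise AlignmentError(
            f"{sam_path}: missing or invalid header: {exc}") from exc
    except OSError as exc:
        raise AlignmentError(f"cannot read {sam_path}: {exc}") from exc
    reads = []
    try:
        with af:
            if not af.references:
                raise AlignmentError(
                    f"{sam_path}: header has no reference sequences")
            for rec in af:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.cigartuples is None:
                    raise AlignmentError(
                        f"{sam_path}: read {rec.query_name!r} has no CIGAR")
                blocks, gaps = _blocks_from_cigar(
                    rec.reference_start, rec.cigartuples)
                reads.append(AlignedRead(
                    name=rec.query_name,
                    reference=rec.reference_name,
                    start=rec.reference_start,
                    cigar=tuple(rec.cigartuples),
                    blocks=blocks,
                    gaps=gaps,
                ))
    except (ValueError, OSError) as exc:
        # pysam reports mid-file CIGAR/record parse errors as either
        raise AlignmentError(f"{sam_path}: malformed record: {exc}") from exc
    return reads


def reference_lengths(sam_path) -> dict[str, int]:
    """Reference name -> length, from the SAM header."""
    try:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=True) as af:
            return dict(zip(af.references, af.lengths))
    except (ValueError, OSError) as exc:
        raise AlignmentError(
            f"{sam_path}: missing or invalid header: {exc}") from exc


def _anchored_gaps(read: AlignedRead, min_anchor: int):
    """Gaps of a read whose flanking blocks are both >= min_anchor long."""
    good, bad = [], 0
    for gi, gap in enumerate(read.gaps):
        left = read.blocks[gi]
        right = read.blocks[gi + 1]
        if (left[1] - left[0]) >= min_anchor and (right[1] - right[0]) >= min_anchor:
            good.append(gap)
        else:
            bad += 1
    return good, bad


def count_junctions(reads, min_anchor: int = 6) -> list[Junction]:
    """Tally N-gap junctions supported by anchor-passing reads.

    Each gap with >= ``min_anchor`` aligned bases on both sides contributes
    one count to the junction keyed by its exact (donor_end, acceptor_start);
    result is sorted by reference then coordinates.
    """
    if min_anchor < 1:
        raise AlignmentError("min_anchor must be >= 1")
    counts = Counter()
    for read in reads:
        good, _ = _anchored_gaps(read, min_anchor)
        for gap in good:
            counts[(read.reference, gap[0], gap[1])] += 1
    return [
        Junction(ref, s, e, c)
        for (ref, s, e), c in sorted(counts.items())
    ]


def _aligned_bases_inside(read: AlignedRead, lo: int, hi: int) -> int:
    return sum(
        max(0, min(b_end, hi) - max(b_start, lo))
        for b_start, b_end in read.blocks
    )


def spliced_fraction(junction: Junction, reads, min_anchor: int = 6):
    """J / (J + I) for one junction; ``None`` when J + I = 0.

    J: reads with an anchor-passing gap exactly equal to the junction.
    I: reads on the same reference with >= ``min_anchor`` aligned bases
    strictly inside the intron and no gap equal to the junction. A read
    contributes to at most one of J or I.
    """
    key = (junction.donor_end, junction.acceptor_start)
    j = i = 0
    for read in reads:
        if read.reference != junction.reference:
            continue
        good, _ = _anchored_gaps(read, min_anchor)
        if key in good:
            j += 1
        elif key not in read.gaps and _aligned_bases_inside(
                read, junction.donor_end, junction.acceptor_start) >= min_anchor:
            i += 1
    if j + i == 0:
        return None
    return j / (j + i)


def quantify_splicing(reads, min_anchor: int = 6) -> SpliceQuantReport:
    """Full junction report: counts plus per-junction spliced fractions."""
    junctions = count_junctions(reads, min_anchor)
    fractions = [spliced_fraction(j, reads, min_anchor) for j in junctions]
    n_bad = sum(_anchored_gaps(r, min_anchor)[1] for r in reads)
    return SpliceQuantReport(
        junctions=junctions,
        spliced_fractions=fractions,
        min_anchor=min_anchor,
        n_reads=len(reads),
        n_anchor_failed_gaps=n_bad,
    )


def coverage_table(reads, ref_lengths: dict[str, int]):
    """Per-base coverage rows (ref, pos, depth) for sashimi-style plots."""
    import numpy as np

    rows = []
    for ref, length in ref_lengths.items():
        depth = np.zeros(length, dtype=np.int64)
        for read in reads:
            if read.reference != ref:
                continue
            for s, e in read.blocks:
                depth[max(0, s):min(length, e)] += 1
        for pos in np.flatnonzero(depth):
            rows.append((ref, int(pos), int(depth[pos])))
    return rows
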