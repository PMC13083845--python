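"""Whole-sequence splice-window and hazard-motif scanning.

This is the audit step run on a construct before synthesis: every position of
a (possibly circular) sequence is tested as a candidate donor 9-mer and/or
acceptor 23-mer on either strand, and simple hazard motifs (restriction sites
known to create splice signals, polyadenylation hexamers) are flagged.

Coordinates are 0-based, half-open, forward-strand. A window on the reverse
strand is reported with the forward-strand interval it occupies and
``strand='-'``. Circular sequences are scanned with a virtual extension
``s + s[:W-1]``; start positions are reported modulo L, so an origin-spanning
window has ``end = start + W > L``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import PatternError
from .model import (
    IUPAC,
    SpliceModel,
    encode_bases,
    obligate_bases,
    obligate_offsets,
    score_windows_array,
    window_length,
)
from .seqio import NucSequence, reverse_complement, write_tsv

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

#: Motifs flagged by default: restriction sites reported to create splice
#: signals when retained in transcripts, and polyadenylation hexamers.
DEFAULT_MOTIFS = {
    "KpnI": "GGTACC",
    "NheI": "GCTAGC",
    "polyA_AATAAA": "AATAAA",
    "polyA_ATTAAA": "ATTAAA",
}


@dataclass(frozen=True, order=True)
class SpliceWindow:
    """A scored candidate splice window.

    ``boundary`` is the forward-strand coordinate of the first intronic base
    (donor) or the first exonic base (acceptor) implied by the window on its
    own strand.
    """

    start: int
    kind: str
    end: int
    strand: str
    boundary: int
    window_seq: str
    score: float


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    pattern: str
    start: int
    end: int
    strand: str
    note: str = ""


@dataclass
class AuditConfig:
    tau: float = 0.0
    kinds: tuple = ("donor", "acceptor")
    strands: tuple = ("+", "-")
    require_canonical: bool = True
    motifs: dict = field(default_factory=lambda: dict(DEFAULT_MOTIFS))


@dataclass
class AuditReport:
    sequence_name: str
    parameters: dict
    windows: list
    motif_hits: list
    n_skipped_n: int

    @property
    def summary(self) -> dict:
        counts = {}
        for w in self.windows:
            key = f"{w.kind}{w.strand}"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def window_rows(self):
        for w in self.windows:
            yield (
                self.sequence_name, w.kind, w.start, w.end, w.strand,
                w.boundary, w.window_seq, f"{w.score:.2f}",
            )

    def to_tsv(self, handle_or_path) -> None:
        meta = dict(self.parameters)
        meta["n_windows_skipped_N"] = self.n_skipped_n
        meta.update({f"count_{k}": v for k, v in sorted(self.summary.items())})
        meta["count_motif_hits"] = len(self.motif_hits)
        rows = list(self.window_rows()) + [
            (self.sequence_name, f"motif:{m.motif_name}", m.start, m.end,
             m.strand, "", m.pattern, "")
            for m in self.motif_hits
        ]
        write_tsv(
            handle_or_path,
            ("seq", "kind", "start", "end", "strand", "boundary",
             "window_seq", "score"),
            rows,
            metadata=meta,
        )

    def to_bed(self, handle_or_path) -> None:
        """BED6 export of splice windows; score = bits clamped to [0, 1000]."""
        rows = [
            (self.sequence_name, w.start, w.end, w.kind,
             int(min(max(w.score, 0.0), 1000.0)), w.strand)
            for w in self.windows
        ]
        write_tsv(handle_or_path, ("#chrom", "start", "end", "name",
                                   "score", "strand"), rows)


def _scan_strand(bases: str, L: int, circular: bool, kind: str,
                 model: SpliceModel, tau: float, require_canonical: bool):
    """Scan one strand's base string; returns (start, seq, score) and N-skips.

    ``bases`` is the strand's own 5'->3' sequence; starts are positions in
    that string (0..L-1 for circular, 0..len-W for linear).
    """
    W = window_length(kind)
    ext = bases + (bases[: W - 1] if circular else "")
    if len(ext) < W:
        return [], 0
    codes = encode_bases(ext)
    wins = sliding_window_view(codes, W)
    if circular:
        wins = wins[:L]
    has_n = (wins == 4).any(axis=1)
    n_skipped = int(has_n.sum())
    keep = ~has_n
    if require_canonical:
        (o1, o2), dinuc = obligate_offsets(kind), obligate_bases(kind)
        keep &= (wins[:, o1] == _BASE_CODE[dinuc[0]]) & (
            wins[:, o2] == _BASE_CODE[dinuc[1]])
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return [], n_skipped
    scores = score_windows_array(wins[idx].astype(np.intp), kind, model)
    hits = []
    for i, sc in zip(idx, scores):
        if sc >= tau:
            hits.append((int(i), ext[i : i + W], float(sc)))
    return hits, n_skipped


def _boundary(kind: str, strand: str, start: int, W: int) -> int:
    # forward-strand coordinate of the first intronic (donor) / exonic
    # (acceptor) base implied by the window on its own strand
    if kind == "donor":
        return start + 3 if strand == "+" else start + (W - 4)
    return start + 20 if strand == "+" else start + (W - 21)


def find_splice_windows(
    seq: NucSequence,
    model: SpliceModel,
    tau: float = 0.0,
    kinds=("donor", "acceptor"),
    strands=("+", "-"),
    require_canonical: bool = True,
) -> list[SpliceWindow]:
    """All windows scoring >= tau, sorted by start then kind.

    With ``require_canonical`` (default) only windows carrying GT (donor) or
    AG (acceptor) at the obligate geometry positions are considered. Windows
    containing N are skipped (see :func:`audit_sequence` for the tally).
    Sequences shorter than the window length yield an empty result.
    """
    windows, _ = _find_with_counts(seq, model, tau, kinds, strands,
                                   require_canonical)
    return windows


def _find_with_counts(seq, model, tau, kinds, strands, require_canonical):
    L = len(seq)
    circular = seq.is_circular
    out = []
    skipped = 0
    for kind in sorted(kinds):
        W = window_length(kind)
        for strand in strands:
            strand_bases = seq.bases if strand == "+" else reverse_complement(seq.bases)
            hits, n_skip = _scan_strand(strand_bases, L, circular, kind,
                                        model, tau, require_canonical)
            skipped += n_skip
            for s_local, wseq, score in hits:
                if strand == "+":
                    start = s_local % L if circular else s_local
                else:
                    # position in reverse-complement coords -> forward interval
                    if circular:
                        start = (L - (s_local + W)) % L
                    else:
                        start = L - (s_local + W)
                out.append(SpliceWindow(
                    start=start,
                    kind=kind,
                    end=start + W,
                    strand=strand,
                    boundary=_boundary(kind, strand, start, W) % L
                    if circular else _boundary(kind, strand, start, W),
                    window_seq=wseq,
                    score=score,
                ))
    out.sort(key=lambda w: (w.start, w.kind, w.strand))
    return out, skipped


def _iupac_regex(pattern: str) -> str:
    parts = []
    for i, ch in enumerate(pattern.upper().replace("U", "T")):
        if ch not in IUPAC:
            raise PatternError(f"invalid IUPAC letter {ch!r} at position {i + 1}")
        options = IUPAC[ch]
        parts.append(options if len(options) == 1 else f"[{options}]")
    return "".join(parts)


def _iupac_revcomp(pattern: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in reversed(pattern.upper().replace("U", "T")))


def scan_motifs(
    seq: NucSequence,
    motifs: dict | None = None,
    strands=("+", "-"),
) -> list[MotifHit]:
    """Find every (possibly overlapping) IUPAC motif match on the requested
    strands; hits are reported as forward-strand intervals."""
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    L = len(seq)
    hits = []
    for name, pattern in motifs.items():
        plen = len(pattern)
        ext = seq.bases + (seq.bases[: plen - 1] if seq.is_circular else "")
        for strand in strands:
            pat = pattern if strand == "+" else _iupac_revcomp(pattern)
            rx = re.compile(f"(?=({_iupac_regex(pat)}))")
            for m in rx.finditer(ext):
                start = m.start()
                if seq.is_circular and start >= L:
                    continue
                start = start % L if seq.is_circular else start
                hits.append(MotifHit(name, pattern, start, start + plen,
                                     strand))
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def audit_sequence(
    seq: NucSequence,
    model: SpliceModel,
    config: AuditConfig | None = None,
) -> AuditReport:
    """Full audit: splice windows plus hazard motifs, with parameter metadata.

    Deterministic for fixed inputs; serialize with :meth:`AuditReport.to_tsv`
    or :meth:`AuditReport.to_bed`.
    """
    if config is None:
        config = AuditConfig()
    windows, skipped = _find_with_counts(
        seq, model, config.tau, config.kinds, config.strands,
        config.require_canonical)
    motif_hits = scan_motifs(seq, config.motifs, config.strands)
    params = {
        "sequence": seq.name,
        "length": len(seq),
        "topology": seq.topology,
        "tau": config.tau,
        "kinds": ",".join(sorted(config.kinds)),
        "strands": ",".join(config.strands),
        "require_canonical": config.require_canonical,
        "model_checksum": model.checksum,
    }
    return AuditReport(seq.name, params, windows, motif_hits, skipped)
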