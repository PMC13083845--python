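"""Design of splice-safe synonymous encodings by silent mutation.

Given a peptide, the designer searches the synonymous codon space for an
encoding with no canonical splice window scoring at or above the threshold
``tau`` (and, optionally, free of forbidden motifs and within GC bounds).
The search is seeded stochastic hill-climbing: start from a random encoding,
repeatedly replace a single codon among the residues overlapped by the current
worst-scoring window with the synonymous alternative that most lowers the
global maximum window score, and restart from a fresh random encoding when no
single-codon move improves. Success is certified by an independent
re-verification of the returned encoding; infeasibility within the restart
budget is reported explicitly (never silently approximated), carrying the best
encoding found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .codonspace import (
    CodonTable,
    _as_peptide,
    max_window_scores,
    standard_table,
)
from .errors import DesignError
from .model import SpliceModel, encode_bases, obligate_offsets, window_length
from .seqio import Peptide


@dataclass(frozen=True)
class OffendingWindow:
    """A window at or above threshold found during verification.

    ``start`` is relative to the encoding's first base and may be negative
    under non-internal flank policies (window extending into left context).
    """

    kind: str
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class SafeEncoding:
    peptide: str
    encoding: str
    max_donor: float | None
    max_acceptor: float | None
    tau: float
    flank_policy: str
    constraints: dict
    iterations: int
    restarts: int
    seed: int


def translate(encoding: str) -> str:
    if len(encoding) % 3:
        raise DesignError(f"encoding length {len(encoding)} is not a codon multiple")
    return str(Seq(encoding).translate())


def _window_scores_by_offset(codes_row: np.ndarray, kind: str,
                             model: SpliceModel, flank_policy: str,
                             flanks) -> list[tuple[int, float]]:
    """(offset, score) for every canonical window of one encoding."""
    from .codonspace import _offsets_for_policy  # shared offset rule

    B = codes_row.shape[0]
    W = window_length(kind)
    o1, o2 = obligate_offsets(kind)
    want = (2, 3) if kind == "donor" else (0, 2)  # G,T / A,G codes
    lut = model.logodds(kind)
    lut_max = lut.max(axis=1)
    left = encode_bases(flanks[0]) if (flanks and flanks[0]) else np.empty(0, np.uint8)
    right = encode_bases(flanks[1]) if (flanks and flanks[1]) else np.empty(0, np.uint8)

    def base_at(pos: int):
        if 0 <= pos < B:
            return int(codes_row[pos])
        if flank_policy == "fixed_flanks":
            if pos < 0 and -pos <= len(left):
                return int(left[len(left) + pos])
            if pos >= B and pos - B < len(right):
                return int(right[pos - B])
        return None  # unknown context

    out = []
    for s in _offsets_for_policy(kind, B, flank_policy, flanks):
        b1, b2 = base_at(s + o1), base_at(s + o2)
        if b1 != want[0] or b2 != want[1]:
            continue
        total = 0.0
        ok = True
        for k in range(W):
            b = base_at(s + k)
            if b is None:
                if flank_policy == "expand_N":
                    total += float(lut_max[k])
                else:
                    ok = False
                    break
            elif b == 4:
                total += float(lut_max[k])
            else:
                total += float(lut[k, b])
        if ok:
            out.append((s, total))
    return out


def verify_encoding(
    encoding: str,
    peptide,
    model: SpliceModel,
    tau: float = 0.0,
    flank_policy: str = "internal_only",
    flanks=None,
) -> tuple[str, list[OffendingWindow]]:
    """Independent check that an encoding is splice-safe for a peptide.

    Returns ``("safe", [])`` when the encoding translates to the peptide and
    hosts no canonical window scoring >= tau under ``flank_policy``, else
    ``("unsafe", offending_windows)``. Length or translation mismatches raise
    :class:`DesignError` (a distinct failure from being unsafe).
    """
    pep = _as_peptide(peptide)
    if len(encoding) != 3 * len(pep):
        raise DesignError(
            f"encoding length {len(encoding)} != 3 x {len(pep)} residues")
    aa = translate(encoding)
    if aa != pep.residues:
        raise DesignError(
            f"translation mismatch: encoding gives {aa!r}, expected "
            f"{pep.residues!r}")
    codes = encode_bases(encoding)
    offending = []
    for kind in ("donor", "acceptor"):
        W = window_length(kind)
        for s, score in _window_scores_by_offset(codes, kind, model,
                                                 flank_policy, flanks):
            if score >= tau:
                offending.append(OffendingWindow(kind, s, s + W, score))
    offending.sort(key=lambda w: (w.start, w.kind))
    return ("safe", []) if not offending else ("unsafe", offending)


def _objective(codes, model, tau, flank_policy, flanks, forbidden, gc_bounds,
               encoding: str):
    """(n_violations, worst_score, constraint_penalty) — lower is better."""
    worst = -np.inf
    n_viol = 0
    for kind in ("donor", "acceptor"):
        for _, score in _window_scores_by_offset(codes, kind, model,
                                                 flank_policy, flanks):
            worst = max(worst, score)
            if score >= tau:
                n_viol += 1
    penalty = 0.0
    for motif in forbidden:
        penalty += encoding.count(motif)
    if gc_bounds is not None:
        gc = (encoding.count("G") + encoding.count("C")) / len(encoding)
        lo, hi = gc_bounds
        penalty += max(0.0, lo - gc) * 100 + max(0.0, gc - hi) * 100
    return n_viol, worst, penalty


def design_safe_encoding(
    peptide,
    model: SpliceModel,
    table: CodonTable | None = None,
    tau: float = 0.0,
    flank_policy: str = "internal_only",
    flanks=None,
    forbidden_motifs=(),
    gc_bounds=None,
    seed: int = 0,
    max_restarts: int = 20,
    max_iters: int = 500,
) -> SafeEncoding:
    """Search for a synonymous encoding with all window scores below ``tau``.

    Deterministic for a given seed. Raises :class:`DesignError` (carrying the
    best encoding found and its max scores) when no feasible encoding is found
    within ``max_restarts`` restarts.
    """
    pep = _as_peptide(peptide)
    table = table or standard_table()
    choices = [table.codons_for(aa) for aa in pep.residues]
    rng = np.random.default_rng(seed)

    def encoding_from(idx):
        return "".join(c[i] for c, i in zip(choices, idx))

    def full_objective(idx):
        enc = encoding_from(idx)
        return _objective(encode_bases(enc), model, tau, flank_policy, flanks,
                          forbidden_motifs, gc_bounds, enc), enc

    def feasible(obj):
        return obj[0] == 0 and obj[2] == 0.0

    best_overall = None  # (obj, encoding)
    total_iters = 0
    for restart in range(max_restarts + 1):
        idx = [int(rng.integers(0, len(c))) for c in choices]
        obj, enc = full_objective(idx)
        for _ in range(max_iters):
            total_iters += 1
            if best_overall is None or obj < best_overall[0]:
                best_overall = (obj, enc)
            if feasible(obj):
                break
            # residues overlapped by the worst-scoring window (or by a
            # forbidden-motif hit when only constraints remain violated)
            target_residues = _residues_to_mutate(
                enc, encode_bases(enc), model, tau, flank_policy, flanks,
                forbidden_motifs, len(pep))
            improved = False
            best_move = None
            for r in target_residues:
                current = idx[r]
                for alt in range(len(choices[r])):
                    if alt == current:
                        continue
                    idx[r] = alt
                    cand_obj, cand_enc = full_objective(idx)
                    if cand_obj < obj and (
                            best_move is None or cand_obj < best_move[0]):
                        best_move = (cand_obj, cand_enc, r, alt)
                    idx[r] = current
            if best_move is not None:
                obj, enc = best_move[0], best_move[1]
                idx[best_move[2]] = best_move[3]
                improved = True
            if not improved:
                break  # local minimum -> restart
        if feasible(obj):
            verdict, offending = verify_encoding(
                enc, pep, model, tau, flank_policy, flanks)
            if verdict != "safe":  # pragma: no cover - soundness guard
                raise DesignError(
                    f"internal error: search result failed verification "
                    f"({offending})")
            codes = encode_bases(enc)[None, :]
            maxd = float(max_window_scores(codes, "donor", model,
                                           flank_policy, flanks)[0])
            maxa = float(max_window_scores(codes, "acceptor", model,
                                           flank_policy, flanks)[0])
            return SafeEncoding(
                peptide=pep.residues,
                encoding=enc,
                max_donor=None if maxd == -np.inf else maxd,
                max_acceptor=None if maxa == -np.inf else maxa,
                tau=tau,
                flank_policy=flank_policy,
                constraints={
                    "forbidden_motifs": tuple(forbidden_motifs),
                    "gc_bounds": gc_bounds,
                },
                iterations=total_iters,
                restarts=restart,
                seed=seed,
            )
    obj, enc = best_overall
    raise DesignError(
        f"no splice-safe encoding of {pep.residues!r} found within "
        f"{max_restarts} restarts (best max score {obj[1]:.2f})",
        best_encoding=enc,
        max_donor=obj[1],
    )


def _residues_to_mutate(enc, codes, model, tau, flank_policy, flanks,
                        forbidden, n_residues):
    """Residue indices overlapped by the worst-scoring window / motif hits."""
    worst = None
    for kind in ("donor", "acceptor"):
        W = window_length(kind)
        for s, score in _window_scores_by_offset(codes, kind, model,
                                                 flank_policy, flanks):
            if worst is None or score > worst[2]:
                worst = (s, s + W, score)
    spans = []
    if worst is not None and worst[2] >= tau:
        spans.append((worst[0], worst[1]))
    else:
        for motif in forbidden:
            p = enc.find(motif)
            if p >= 0:
                spans.append((p, p + len(motif)))
        if not spans and worst is not None:
            spans.append((worst[0], worst[1]))
    residues = set()
    for lo, hi in spans:
        lo_r = max(0, lo // 3)
        hi_r = min(n_residues - 1, (hi - 1) // 3)
        residues.update(range(lo_r, hi_r + 1))
    return sorted(residues) or list(range(n_residues))
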