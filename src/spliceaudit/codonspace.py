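"""Synonymous codon-space enumeration/sampling and splice-risk profiling.

A peptide of length ``L`` has ``prod(degeneracy(aa_i))`` synonymous DNA
encodings. Short peptides (epitope tags, linker units) are enumerated
exhaustively; longer ones are profiled by uniform Monte-Carlo sampling of one
codon per residue. For each encoding the maximum donor and acceptor window
scores are computed and an encoding is called splicing-prone when that maximum
reaches the threshold ``tau`` (0 bits by default, the conventional putative-
site cutoff).

Flank policies decide which windows an encoding can host:

* ``internal_only`` (default) — only windows lying fully inside the encoding;
* ``expand_N`` — the obligate GT/AG must lie inside the encoding but the rest
  of the window may extend into unknown context, scored worst-case (each
  out-of-encoding position contributes its maximum log-odds over the four
  bases);
* ``fixed_flanks`` — the encoding is scored embedded in caller-supplied
  left/right context, counting windows whose obligate dinucleotide overlaps
  the encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from .errors import CodonSpaceError
from .model import (
    SpliceModel,
    encode_bases,
    obligate_offsets,
    window_length,
)
from .seqio import Peptide

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

#: Common epitope-tag and linker presets (one-letter amino acids).
TAG_PRESETS = {
    "FLAG": "DYKDDDDK",
    "HA": "YPYDVPDYA",
    "Myc": "EQKLISEEDL",
    "V5": "GKPIPNPLLGLDST",
    "6xHis": "HHHHHH",
    "GS_linker": "GGGGS",
}

FLANK_POLICIES = ("internal_only", "expand_N", "fixed_flanks")


@dataclass(frozen=True)
class CodonTable:
    """Residue -> synonymous codons under the standard genetic code.

    Stop codons are never included; codons per residue are sorted so that
    exhaustive enumeration order is well defined.
    """

    codons: dict

    @classmethod
    def standard(cls) -> "CodonTable":
        fwd = _BioCodonTable.standard_dna_table.forward_table
        mapping: dict[str, list] = {}
        for codon, aa in fwd.items():
            mapping.setdefault(aa, []).append(codon.upper())
        return cls({aa: tuple(sorted(cs)) for aa, cs in mapping.items()})

    def codons_for(self, residue: str) -> tuple:
        try:
            return self.codons[residue]
        except KeyError:
            raise CodonSpaceError(f"unknown residue {residue!r}") from None

    def degeneracy(self, residue: str) -> int:
        return len(self.codons_for(residue))


_STANDARD_TABLE = None


def standard_table() -> CodonTable:
    global _STANDARD_TABLE
    if _STANDARD_TABLE is None:
        _STANDARD_TABLE = CodonTable.standard()
    return _STANDARD_TABLE


def _as_peptide(peptide) -> Peptide:
    if isinstance(peptide, Peptide):
        return peptide
    return Peptide("peptide", str(peptide))


def count_encodings(peptide, table: CodonTable | None = None) -> int:
    """Exact number of synonymous encodings (product of degeneracies)."""
    pep = _as_peptide(peptide)
    table = table or standard_table()
    return math.prod(table.degeneracy(aa) for aa in pep.residues)


def generate_encodings(
    peptide,
    table: CodonTable | None = None,
    mode: str = "exhaustive",
    n: int | None = None,
    seed: int | None = None,
    cap: int = 10**6,
):
    """Stream synonymous DNA encodings of ``peptide``.

    ``exhaustive`` yields each encoding exactly once in lexicographic codon
    order and requires the space to be at most ``cap``. ``sampled`` draws each
    residue's codon independently and uniformly (duplicates retained),
    reproducibly for a given ``seed``.
    """
    pep = _as_peptide(peptide)
    table = table or standard_table()
    choices = [table.codons_for(aa) for aa in pep.residues]
    if mode == "exhaustive":
        total = count_encodings(pep, table)
        if total > cap:
            raise CodonSpaceError(
                f"{total} encodings exceed the exhaustive cap {cap}")
        yield from ("".join(t) for t in product(*choices))
    elif mode == "sampled":
        if n is None or n < 1:
            raise CodonSpaceError("sampled mode requires n >= 1")
        if seed is None:
            raise CodonSpaceError("sampled mode requires a seed")
        rng = np.random.default_rng(seed)
        degs = np.array([len(c) for c in choices])
        for _ in range(n):
            idx = rng.integers(0, degs)
            yield "".join(c[i] for c, i in zip(choices, idx))
    else:
        raise CodonSpaceError(f"unknown mode {mode!r}")


# -- vectorized window-score machinery ---------------------------------------

def _codon_base_codes(table: CodonTable, residues: str):
    """Per-residue (degeneracy, 3) arrays of base codes for each codon."""
    return [
        np.array([[_BASE_CODE[b] for b in codon]
                  for codon in table.codons_for(aa)], dtype=np.intp)
        for aa in residues
    ]


def _offsets_for_policy(kind: str, n_bases: int, policy: str,
                        flanks: tuple[str, str] | None):
    """Window start offsets (relative to encoding base 0) under a policy."""
    W = window_length(kind)
    o1, o2 = obligate_offsets(kind)
    if policy == "internal_only":
        return range(0, n_bases - W + 1)
    if policy == "expand_N":
        # obligate dinucleotide fully inside the encoding
        return range(-o1, n_bases - 1 - o2 + 1)
    if policy == "fixed_flanks":
        if flanks is None:
            raise CodonSpaceError("fixed_flanks policy requires flank strings")
        left, right = flanks
        # obligate dinucleotide must overlap the encoding by >= 1 base
        starts = []
        for s in range(-len(left), n_bases + len(right) - W + 1):
            d1, d2 = s + o1, s + o2
            if d2 < 0 or d1 > n_bases - 1:
                continue
            if s < -len(left) or s + W > n_bases + len(right):
                continue
            starts.append(s)
        return starts
    raise CodonSpaceError(f"unknown flank policy {policy!r}")


def max_window_scores(
    codes: np.ndarray,
    kind: str,
    model: SpliceModel,
    flank_policy: str = "internal_only",
    flanks: tuple[str, str] | None = None,
) -> np.ndarray:
    """Max canonical-window score per row of an (n, B) base-code array.

    Rows without any canonical (GT/AG-bearing) window yield -inf, the
    "no window of this kind" marker. Out-of-encoding positions are scored
    worst-case (``expand_N``) or from the literal flanks (``fixed_flanks``).
    """
    if codes.ndim != 2:
        raise ValueError("codes must be 2-D (n encodings x B bases)")
    n, B = codes.shape
    W = window_length(kind)
    o1, o2 = obligate_offsets(kind)
    lut = model.logodds(kind)
    lut_max = lut.max(axis=1)
    dinuc = "GT" if kind == "donor" else "AG"
    c1, c2 = _BASE_CODE[dinuc[0]], _BASE_CODE[dinuc[1]]

    left_codes = right_codes = None
    if flank_policy == "fixed_flanks" and flanks is not None:
        left_codes = encode_bases(flanks[0]) if flanks[0] else np.empty(0, dtype=np.uint8)
        right_codes = encode_bases(flanks[1]) if flanks[1] else np.empty(0, dtype=np.uint8)

    def base_col(pos: int, win_pos: int):
        """Column of base codes at encoding-relative position ``pos``.

        Returns (codes_column or None, fixed_logodds). None column with a
        float means every row takes that fixed contribution.
        """
        if 0 <= pos < B:
            return codes[:, pos], None
        if flank_policy == "expand_N":
            return None, float(lut_max[win_pos])
        if flank_policy == "fixed_flanks":
            if pos < 0 and left_codes is not None and -pos <= len(left_codes):
                b = int(left_codes[len(left_codes) + pos])
                return None, float(lut[win_pos, b]) if b < 4 else float(lut_max[win_pos])
            if pos >= B and right_codes is not None and pos - B < len(right_codes):
                b = int(right_codes[pos - B])
                return None, float(lut[win_pos, b]) if b < 4 else float(lut_max[win_pos])
        raise CodonSpaceError(f"window position {pos} outside scoreable range")

    best = np.full(n, -np.inf)
    for s in _offsets_for_policy(kind, B, flank_policy, flanks):
        # canonical mask at the obligate dinucleotide
        mask = np.ones(n, dtype=bool)
        for pos, want in ((s + o1, c1), (s + o2, c2)):
            col, fixed = base_col(pos, pos - s)
            if col is not None:
                mask &= col == want
            else:
                # literal flank base: window exists for all rows or none
                b_ok = False
                if flank_policy == "fixed_flanks":
                    fc = left_codes if pos < 0 else right_codes
                    i = len(left_codes) + pos if pos < 0 else pos - B
                    b_ok = int(fc[i]) == want
                if not b_ok:
                    mask &= False
        if not mask.any():
            continue
        total = np.zeros(n)
        for k in range(W):
            col, fixed = base_col(s + k, k)
            if col is None:
                total += fixed
            else:
                total += lut[k, col]
        best = np.where(mask, np.maximum(best, total), best)
    return best


@dataclass(frozen=True)
class RiskProfile:
    """Aggregate splice risk of a codon-encoding ensemble.

    ``prone5_fraction``/``prone3_fraction`` are the proportions of encodings
    whose max donor/acceptor window score reaches ``tau``;
    ``prone_both_fraction`` requires both in the same encoding. Encodings with
    no canonical window of a kind count as not prone for that kind.
    """

    peptide: str
    n_evaluated: int
    mode: str
    seed: int | None
    tau: float
    flank_policy: str
    prone5_fraction: float
    prone3_fraction: float
    prone_both_fraction: float
    max_donor_scores: np.ndarray | None = None
    max_acceptor_scores: np.ndarray | None = None

    def __post_init__(self):
        if not (self.prone_both_fraction
                <= min(self.prone5_fraction, self.prone3_fraction) + 1e-12):
            raise CodonSpaceError("inconsistent prone fractions")

    def summary_rows(self):
        yield ("peptide", self.peptide)
        yield ("n_evaluated", self.n_evaluated)
        yield ("mode", self.mode)
        yield ("seed", self.seed)
        yield ("tau", self.tau)
        yield ("flank_policy", self.flank_policy)
        yield ("prone5_fraction", f"{self.prone5_fraction:.6f}")
        yield ("prone3_fraction", f"{self.prone3_fraction:.6f}")
        yield ("prone_both_fraction", f"{self.prone_both_fraction:.6f}")


def _exhaustive_codes(choices, chunk: int):
    """Yield (m, 3L) base-code chunks over the full lexicographic product."""
    buf = []
    for combo in product(*[range(len(c)) for c in choices]):
        buf.append(np.concatenate([choices[i][j] for i, j in enumerate(combo)]))
        if len(buf) == chunk:
            yield np.stack(buf)
            buf = []
    if buf:
        yield np.stack(buf)


def _sampled_codes(choices, n: int, seed: int, chunk: int):
    rng = np.random.default_rng(seed)
    degs = np.array([len(c) for c in choices])
    L = len(choices)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        idx = rng.integers(0, degs, size=(m, L))
        rows = np.empty((m, 3 * L), dtype=np.intp)
        for i, ch in enumerate(choices):
            rows[:, 3 * i : 3 * i + 3] = ch[idx[:, i]]
        yield rows
        done += m


def risk_profile(
    peptide,
    model: SpliceModel,
    table: CodonTable | None = None,
    mode: str = "sampled",
    n: int = 10**5,
    seed: int | None = None,
    tau: float = 0.0,
    flank_policy: str = "internal_only",
    flanks: tuple[str, str] | None = None,
    keep_scores: bool = False,
    chunk: int = 100_000,
    cap: int = 10**6,
) -> RiskProfile:
    """Splice-risk profile of the synonymous encoding ensemble of ``peptide``.

    For every encoding the maximum donor score over canonical donor windows
    and the maximum acceptor score over canonical acceptor windows (under
    ``flank_policy``) are computed; the profile reports the fractions of
    encodings at or above ``tau`` for either and both kinds.
    """
    pep = _as_peptide(peptide)
    table = table or standard_table()
    if flank_policy not in FLANK_POLICIES:
        raise CodonSpaceError(f"unknown flank policy {flank_policy!r}")
    choices = _codon_base_codes(table, pep.residues)
    if mode == "exhaustive":
        total = count_encodings(pep, table)
        if total > cap:
            raise CodonSpaceError(
                f"{total} encodings exceed the exhaustive cap {cap}")
        chunks = _exhaustive_codes(choices, chunk)
    elif mode == "sampled":
        if n < 1:
            raise CodonSpaceError("sampled mode requires n >= 1")
        if seed is None:
            raise CodonSpaceError("sampled mode requires a seed")
        chunks = _sampled_codes(choices, n, seed, chunk)
    else:
        raise CodonSpaceError(f"unknown mode {mode!r}")

    n_eval = 0
    n5 = n3 = nboth = 0
    all5, all3 = [], []
    for codes in chunks:
        d = max_window_scores(codes, "donor", model, flank_policy, flanks)
        a = max_window_scores(codes, "acceptor", model, flank_policy, flanks)
        prone5 = d >= tau
        prone3 = a >= tau
        n_eval += codes.shape[0]
        n5 += int(prone5.sum())
        n3 += int(prone3.sum())
        nboth += int((prone5 & prone3).sum())
        if keep_scores:
            all5.append(d)
            all3.append(a)
    return RiskProfile(
        peptide=pep.residues,
        n_evaluated=n_eval,
        mode=mode,
        seed=seed if mode == "sampled" else None,
        tau=tau,
        flank_policy=flank_policy,
        prone5_fraction=n5 / n_eval,
        prone3_fraction=n3 / n_eval,
        prone_both_fraction=nboth / n_eval,
        max_donor_scores=np.concatenate(all5) if keep_scores else None,
        max_acceptor_scores=np.concatenate(all3) if keep_scores else None,
    )


def linker_prone_curve(
    unit,
    repeats,
    model: SpliceModel,
    table: CodonTable | None = None,
    n: int = 10**4,
    seed: int = 0,
    tau: float = 0.0,
    flank_policy: str = "internal_only",
) -> list[tuple[int, float, int]]:
    """Donor-prone fraction of codon-randomized ``unit`` x k linkers.

    Returns one ``(k, prone5_fraction, n_evaluated)`` tuple per repeat count.
    Sampling is seeded per repeat count (seed + k) so the curve is
    reproducible and lengths are independent draws.
    """
    if n < 1:
        raise CodonSpaceError("n per length must be >= 1")
    unit_pep = _as_peptide(unit)
    out = []
    for k in repeats:
        if k < 1:
            raise CodonSpaceError("repeat counts must be >= 1")
        pep = Peptide(f"{unit_pep.name}x{k}", unit_pep.residues * k)
        prof = risk_profile(
            pep, model, table, mode="sampled", n=n, seed=seed + k,
            tau=tau, flank_policy=flank_policy,
        )
        out.append((k, prof.prone5_fraction, prof.n_evaluated))
    return out
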