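"""Maximum-entropy scoring of candidate 5' (donor) and 3' (acceptor) splice sites.

The model scores a fixed-geometry window as the log2-odds of the window under
a maximum-entropy model of authentic human splice sites versus a background
(null) composition:

    score(w) = log2( P_site(w) / P_background(w) )

The site model is the maximum-entropy distribution consistent with positional
(first-order) nucleotide-frequency constraints estimated from annotated human
splice sites, which factorizes into independent per-position terms; the
obligate dinucleotide (GT for donors, AG for acceptors) enters through its own
consensus-odds term exactly like the non-consensus positions, so non-canonical
windows are scoreable but heavily penalized. Scores are in bits; >= 0 is the
conventional operating threshold for calling a window a putative splice site.

Window geometry (single source of truth for all modules):

* donor: 9-mer, 3 exonic + 6 intronic bases, GT at window positions 4-5
  (1-based), i.e. the exon|intron boundary sits after window position 3;
* acceptor: 23-mer, 18 tract bases + AG at positions 19-20 + 3 exonic bases,
  i.e. the intron|exon boundary sits after window position 20.

Parameter tables are packaged plain-text fixtures (see ``spliceaudit/data``),
an in-package synthetic reconstruction from published positional frequencies
of human splice sites; their sha256 checksums are verified at load time and a
combined model checksum is stamped into every report.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import product

import numpy as np

from .errors import ModelError, PatternError, SequenceError
from .seqio import normalize_sequence

DONOR_LENGTH = 9
DONOR_EXON_PREFIX = 3  # window positions 1-3 are exonic
DONOR_DINUCLEOTIDE = (3, 4)  # 0-based window offsets of the obligate GT
ACCEPTOR_LENGTH = 23
ACCEPTOR_INTRON_PREFIX = 20  # window positions 1-20 are intronic
ACCEPTOR_DINUCLEOTIDE = (18, 19)  # 0-based window offsets of the obligate AG
ACCEPTOR_EXON_SUFFIX = 3

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_DATA_CHECKSUMS = {
    "donor_frequencies.tsv": "5c5e72b3e5cf37f6b45f560f852c6bd23bf8907ddbc4e243825000634a4ea7bf",
    "acceptor_frequencies.tsv": "168ca2f5a44d417014f89ecbc3003f977663f657e44a8da6d29e2f433772ee50",
    "background_frequencies.tsv": "73a5e75f934fd7a3e88965d3ecf577495fa95144e28228c7aac425f606fc7617",
}


@dataclass(frozen=True)
class SpliceModel:
    """Loaded splice-site model: per-position log2-odds lookup tables.

    ``donor_logodds`` is a (9, 4) array and ``acceptor_logodds`` a (23, 4)
    array of log2(f_pos(base) / background(base)); row order follows window
    position, column order A, C, G, T. ``donor_freqs``/``acceptor_freqs`` keep
    the raw probability tables for independent (non-lookup) scoring routes.
    """

    donor_freqs: np.ndarray
    acceptor_freqs: np.ndarray
    background: np.ndarray
    checksum: str
    donor_logodds: np.ndarray = field(init=False, repr=False)
    acceptor_logodds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        for name, table, length in (
            ("donor", self.donor_freqs, DONOR_LENGTH),
            ("acceptor", self.acceptor_freqs, ACCEPTOR_LENGTH),
        ):
            if table.shape != (length, 4):
                raise ModelError(f"{name} table must be ({length}, 4), got {table.shape}")
            if not np.all(np.isfinite(table)) or np.any(table <= 0):
                raise ModelError(f"{name} table entries must be finite and positive")
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ModelError("background must be 4 positive frequencies")
        donor_lo = np.log2(self.donor_freqs / self.background)
        acceptor_lo = np.log2(self.acceptor_freqs / self.background)
        for arr in (self.donor_freqs, self.acceptor_freqs, self.background,
                    donor_lo, acceptor_lo):
            arr.setflags(write=False)
        object.__setattr__(self, "donor_logodds", donor_lo)
        object.__setattr__(self, "acceptor_logodds", acceptor_lo)

    def logodds(self, kind: str) -> np.ndarray:
        if kind == "donor":
            return self.donor_logodds
        if kind == "acceptor":
            return self.acceptor_logodds
        raise ValueError(f"unknown window kind {kind!r}")


def window_length(kind: str) -> int:
    if kind == "donor":
        return DONOR_LENGTH
    if kind == "acceptor":
        return ACCEPTOR_LENGTH
    raise ValueError(f"unknown window kind {kind!r}")


def obligate_offsets(kind: str) -> tuple[int, int]:
    """0-based window offsets of the obligate dinucleotide (GT or AG)."""
    return DONOR_DINUCLEOTIDE if kind == "donor" else ACCEPTOR_DINUCLEOTIDE


def obligate_bases(kind: str) -> str:
    return "GT" if kind == "donor" else "AG"


def _read_table(name: str, n_rows: int) -> np.ndarray:
    ref = resources.files("spliceaudit.data").joinpath(name)
    try:
        text = ref.read_bytes()
    except FileNotFoundError as exc:
        raise ModelError(
            f"model table {name} missing (expected sha256 {_DATA_CHECKSUMS[name]})"
        ) from exc
    digest = hashlib.sha256(text).hexdigest()
    if digest != _DATA_CHECKSUMS[name]:
        raise ModelError(
            f"model table {name} corrupt: sha256 {digest}, "
            f"expected {_DATA_CHECKSUMS[name]}"
        )
    rows = []
    for line in text.decode().splitlines():
        if not line or line.startswith("#") or line.startswith(("position", "base")):
            continue
        rows.append(line.split("\t"))
    if name.startswith("background"):
        freqs = {r[0]: float(r[1]) for r in rows}
        return np.array([freqs[b] for b in BASES])
    table = np.array([[float(v) for v in r[1:5]] for r in rows])
    if table.shape[0] != n_rows:
        raise ModelError(f"model table {name}: expected {n_rows} rows, got {table.shape[0]}")
    return table


def load_model() -> SpliceModel:
    """Load the packaged splice-site model, verifying table checksums.

    Loading is deterministic: two loads produce identical tables and the same
    combined checksum (the sha256 over the three table digests, truncated to
    12 hex characters), which scanners stamp into report metadata.
    """
    donor = _read_table("donor_frequencies.tsv", DONOR_LENGTH)
    acceptor = _read_table("acceptor_frequencies.tsv", ACCEPTOR_LENGTH)
    background = _read_table("background_frequencies.tsv", 4)
    combined = hashlib.sha256(
        "".join(_DATA_CHECKSUMS[k] for k in sorted(_DATA_CHECKSUMS)).encode()
    ).hexdigest()[:12]
    return SpliceModel(donor, acceptor, background, combined)


def encode_bases(seq: str) -> np.ndarray:
    """Map a normalized DNA string to integer codes A=0 C=1 G=2 T=3 N=4."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if np.any(out == 255):
        bad = int(np.argmax(out == 255))
        raise SequenceError(f"invalid base {seq[bad]!r} at position {bad + 1}")
    return out


def _validated_window(window: str, kind: str) -> str:
    win = normalize_sequence(window)
    need = window_length(kind)
    if len(win) != need:
        raise SequenceError(
            f"{kind} window must be {need} nt, got {len(win)}"
        )
    for i, ch in enumerate(win):
        if ch not in BASES:
            raise SequenceError(f"invalid base {ch!r} at position {i + 1}")
    return win


def score_window(window: str, kind: str, model: SpliceModel) -> float:
    """Score one literal window (donor 9-mer or acceptor 23-mer) in bits."""
    win = _validated_window(window, kind)
    lut = model.logodds(kind)
    idx = encode_bases(win)
    return float(lut[np.arange(len(win)), idx].sum())


def score_donor(window: str, model: SpliceModel) -> float:
    """log2-odds (bits) of a 9-mer under the donor model vs background."""
    return score_window(window, "donor", model)


def score_acceptor(window: str, model: SpliceModel) -> float:
    """log2-odds (bits) of a 23-mer under the acceptor model vs background."""
    return score_window(window, "acceptor", model)


def score_window_naive(window: str, kind: str, model: SpliceModel) -> float:
    """Independent scoring route: probability ratio in linear space.

    Computes P_site(w) and P_background(w) as explicit float products over the
    frequency tables and takes a single log2 at the end — no lookup-table
    log-odds sums. Used as the in-repo cross-check for the production scorer.
    """
    win = _validated_window(window, kind)
    freqs = model.donor_freqs if kind == "donor" else model.acceptor_freqs
    p_site = 1.0
    p_bgd = 1.0
    for pos, base in enumerate(win):
        j = _BASE_INDEX[base]
        p_site *= float(freqs[pos, j])
        p_bgd *= float(model.background[j])
    return math.log2(p_site / p_bgd)


def score_windows_array(codes: np.ndarray, kind: str, model: SpliceModel) -> np.ndarray:
    """Vectorized scoring of an (n, W) integer-coded window array (no N)."""
    lut = model.logodds(kind)
    if codes.ndim != 2 or codes.shape[1] != window_length(kind):
        raise ValueError(f"expected (n, {window_length(kind)}) array")
    return lut[np.arange(codes.shape[1]), codes].sum(axis=1)


def expand_iupac(pattern: str, cap: int = 65536):
    """Yield every literal expansion of an IUPAC DNA pattern.

    Raises :class:`PatternError` for invalid letters or when the number of
    combinations (product of per-letter degeneracies) exceeds ``cap``.
    """
    pattern = pattern.upper().replace("U", "T")
    choices = []
    n = 1
    for i, ch in enumerate(pattern):
        if ch not in IUPAC:
            raise PatternError(f"invalid IUPAC letter {ch!r} at position {i + 1}")
        choices.append(IUPAC[ch])
        n *= len(IUPAC[ch])
    if n > cap:
        raise PatternError(f"pattern expands to {n} combinations (cap {cap})")
    return ("".join(t) for t in product(*choices))


def count_expansions(pattern: str) -> int:
    n = 1
    for ch in pattern.upper().replace("U", "T"):
        if ch not in IUPAC:
            raise PatternError(f"invalid IUPAC letter {ch!r}")
        n *= len(IUPAC[ch])
    return n


@dataclass(frozen=True)
class AmbiguousScoreSummary:
    """Score statistics over every literal expansion of an IUPAC pattern."""

    pattern: str
    kind: str
    n_expansions: int
    min_score: float
    max_score: float
    fraction_ge_tau: float
    tau: float


def summarize_ambiguous(
    pattern: str,
    kind: str,
    tau: float,
    model: SpliceModel,
    cap: int = 65536,
) -> AmbiguousScoreSummary:
    """Expand an IUPAC pattern, score every combination, and summarize.

    The pattern length must match the window geometry of ``kind``. Returns
    min/max scores, the fraction scoring >= ``tau``, and the expansion count.
    """
    pattern = pattern.upper().replace("U", "T")
    need = window_length(kind)
    if len(pattern) != need:
        raise PatternError(
            f"{kind} pattern must be {need} letters, got {len(pattern)}"
        )
    scores = [score_window(w, kind, model) for w in expand_iupac(pattern, cap)]
    arr = np.array(scores)
    return AmbiguousScoreSummary(
        pattern=pattern,
        kind=kind,
        n_expansions=len(scores),
        min_score=float(arr.min()),
        max_score=float(arr.max()),
        fraction_ge_tau=float(np.mean(arr >= tau)),
        tau=tau,
    )
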