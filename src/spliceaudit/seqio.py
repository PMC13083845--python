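"""Reading, validation, and normalization of DNA and peptide inputs.

DNA is held as plain uppercase strings over ``{A, C, G, T, N}``; coordinates
everywhere in the package are 0-based, half-open, on the forward strand of the
stored sequence. Circular topology (plasmids) is carried on the record and
interpreted by the scanner via virtual extension.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FileFormatError, SequenceError

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(raw: str) -> str:
    """Normalize a raw nucleotide string to uppercase ``{A,C,G,T,N}`` DNA.

    Uppercases, converts RNA U to T, and strips whitespace and digits (so
    GenBank-style numbered blocks paste cleanly). Any residual character
    outside the alphabet raises :class:`SequenceError` naming the character
    and its 1-based position in the cleaned sequence.
    """
    if not raw:
        raise SequenceError("empty sequence")
    cleaned = []
    for ch in raw:
        if ch.isspace() or ch.isdigit():
            continue
        cleaned.append(ch)
    seq = "".join(cleaned).upper().replace("U", "T")
    if not seq:
        raise SequenceError("empty sequence after normalization")
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise SequenceError(f"invalid base {ch!r} at position {i + 1}")
    return seq


def reverse_complement(bases: str) -> str:
    """Watson-Crick reverse complement of a normalized DNA string (N -> N)."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A validated DNA sequence with a name and topology.

    ``topology`` is ``"linear"`` or ``"circular"``; plasmids are circular and
    scanners treat windows spanning the origin as real.
    """

    name: str
    bases: str
    topology: str = "linear"

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "bases", normalize_sequence(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.name, reverse_complement(self.bases), self.topology)


@dataclass(frozen=True)
class Peptide:
    """A validated one-letter amino-acid sequence (20 standard residues)."""

    name: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise SequenceError("empty peptide")
        residues = self.residues.upper()
        for i, ch in enumerate(residues):
            if ch not in AA_ALPHABET:
                raise SequenceError(
                    f"invalid amino acid {ch!r} at position {i + 1}"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


def read_sequences(path, fmt: str = "fasta") -> list[NucSequence]:
    """Read DNA records from FASTA or GenBank into :class:`NucSequence`.

    GenBank circular topology annotations are honored; FASTA records default
    to linear. Raises :class:`FileFormatError` for unreadable, malformed, or
    empty files and :class:`SequenceError` for records with invalid bases.
    """
    if fmt not in ("fasta", "genbank"):
        raise FileFormatError(f"unsupported format {fmt!r}")
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except OSError as exc:
        raise FileFormatError(f"cannot read {path}: {exc}") from exc
    except ValueError as exc:
        raise FileFormatError(f"malformed {fmt} file {path}: {exc}") from exc
    if not records:
        raise FileFormatError(f"no {fmt} records in {path}")
    out = []
    for rec in records:
        topology = "linear"
        if fmt == "genbank":
            if rec.annotations.get("topology", "").lower() == "circular":
                topology = "circular"
        try:
            out.append(NucSequence(rec.id, str(rec.seq), topology))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[NucSequence], handle_or_path) -> None:
    """Write sequences as FASTA (name and bases round-trip exactly)."""
    records = [
        SeqRecord(Seq(s.bases), id=s.name, description="") for s in seqs
    ]
    if hasattr(handle_or_path, "write"):
        SeqIO.write(records, handle_or_path, "fasta")
    else:
        with open(handle_or_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


def write_tsv(
    handle_or_path,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    metadata: dict | None = None,
) -> None:
    """Write a TSV report: '#'-prefixed metadata lines, header, then rows."""

    def _write(fh: TextIO):
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")

    if hasattr(handle_or_path, "write"):
        _write(handle_or_path)
    elif handle_or_path in (None, "-"):
        _write(sys.stdout)
    else:
        with open(handle_or_path, "w") as fh:
            _write(fh)


def iter_tsv(path) -> Iterator[list[str]]:
    """Yield data rows of a TSV report, skipping metadata and header."""
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            yield line.split("\t")
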