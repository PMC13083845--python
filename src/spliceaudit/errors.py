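"""Exception hierarchy for spliceaudit.

Every user-facing failure derives from :class:`SpliceAuditError` so the CLI
can distinguish usage errors from runtime failures with a single except.
"""


class SpliceAuditError(Exception):
    """Base class for all spliceaudit errors."""


class SequenceError(SpliceAuditError):
    """Invalid nucleotide or peptide sequence."""


class FileFormatError(SpliceAuditError):
    """Unreadable, empty, or malformed input file."""


class ModelError(SpliceAuditError):
    """Missing or corrupt splice-model parameter table."""


class PatternError(SpliceAuditError):
    """Invalid IUPAC pattern or expansion budget exceeded."""


class CodonSpaceError(SpliceAuditError):
    """Invalid peptide/codon-space request (unknown residue, cap exceeded)."""


class DesignError(SpliceAuditError):
    """Splice-safe encoding search failed or verification mismatch."""

    def __init__(self, message, best_encoding=None, max_donor=None, max_acceptor=None):
        super().__init__(message)
        self.best_encoding = best_encoding
        self.max_donor = max_donor
        self.max_acceptor = max_acceptor


class AlignmentError(SpliceAuditError):
    """Malformed SAM input (bad CIGAR, missing header)."""
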