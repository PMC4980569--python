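"""Alphabet rules, motif validation and reverse complementation.

This is the vocabulary module: every other part of the package talks in
upper-case DNA strings over {A, C, G, T} ("motifs") and a two-valued
strand. Exact matching is the whole game downstream, so motifs are
validated strictly here — ambiguity codes (N, IUPAC degenerate bases)
are rejected rather than expanded, because an exact matcher that allows
no mismatch at any position has no defined semantics for them.
"""

from __future__ import annotations

from enum import Enum

__all__ = [
    "DNA_BASES",
    "MotifError",
    "Strand",
    "validate_motif",
    "complement",
    "revcomp",
    "is_palindromic",
]

DNA_BASES = frozenset("ACGT")

# N maps to N so genome-side sequences (which may contain runs of
# undetermined bases) can be complemented; query motifs never contain N.
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifError(ValueError):
    """Raised when query text is not a valid DNA motif."""


class Strand(str, Enum):
    """DNA strand of a genomic interval: forward (+) or reverse (-)."""

    PLUS = "+"
    MINUS = "-"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value

    @classmethod
    def from_symbol(cls, symbol: str) -> "Strand":
        """Parse '+', '-', 'plus' or 'minus' (case-insensitive)."""
        s = str(symbol).strip().lower()
        if s in ("+", "plus", "fwd", "forward"):
            return cls.PLUS
        if s in ("-", "minus", "rev", "reverse"):
            return cls.MINUS
        raise ValueError(f"unknown strand symbol {symbol!r}")

    @property
    def opposite(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS


def validate_motif(text: str) -> str:
    """Normalize and validate a raw query sequence.

    Surrounding whitespace is stripped and the sequence is upper-cased
    (FASTA soft-masking must not affect exact matching). Every remaining
    character must be one of A, C, G, T.

    Returns the normalized motif string.

    Raises
    ------
    MotifError
        ``"empty motif"`` for empty/whitespace-only input;
        ``"invalid base ... at position i"`` (1-based) for any character
        outside {A, C, G, T}, including N and IUPAC degenerate codes.
    """
    if text is None:
        raise MotifError("empty motif")
    m = str(text).strip().upper()
    if not m:
        raise MotifError("empty motif")
    for i, ch in enumerate(m, start=1):
        if ch not in DNA_BASES:
            raise MotifError(f"invalid base {ch!r} at position {i}")
    return m


def complement(base: str) -> str:
    """Complement of a single base (N stays N)."""
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence; an involution."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindromic(motif: str) -> bool:
    """True iff the motif equals its own reverse complement.

    A palindromic motif matches at the same loci on both strands, so its
    genome-wide occurrence total (summed over strands) is always even —
    such a motif can never be unique in the both-strand sense.
    """
    return motif == revcomp(motif)
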