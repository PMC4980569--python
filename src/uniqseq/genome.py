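"""Genome containers, FASTA I/O and locus/flank addressing.

Coordinates are 1-based and fully closed throughout the library, matching
the user-facing "starting position" convention of the tools this package
implements. Exported BED6 converts to 0-based half-open.

Minus-strand loci are addressed by the leftmost *forward* coordinate plus
a strand flag; their sequence is read 5'->3' along the minus strand,
i.e. it is the reverse complement of the forward bases of the interval.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .core import Strand, complement, revcomp

__all__ = [
    "GENOME_BASES",
    "GenomeError",
    "LocusError",
    "Side",
    "FlankSignal",
    "Chromosome",
    "Genome",
    "GenomicLocus",
    "load_genome",
    "write_fasta",
    "locus_sequence",
    "flank_base",
    "read_locus_table",
    "write_locus_table",
    "loci_to_bed6",
]

GENOME_BASES = frozenset("ACGTN")


class GenomeError(ValueError):
    """Malformed genome input (FASTA structure, characters, ids)."""


class LocusError(ValueError):
    """A locus that does not address valid genome sequence."""


class Side(str, Enum):
    """Which end of a motif, in the motif's own 5'->3' reading frame."""

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


class FlankSignal(Enum):
    """Why a flanking base could not be returned."""

    BOUNDARY = "boundary"  # requested coordinate falls off the chromosome
    AMBIGUOUS = "ambiguous"  # the genomic base there is N


@dataclass(frozen=True)
class Chromosome:
    """One named sequence over {A,C,G,T,N}, stored upper-case."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


class Genome:
    """An ordered collection of uniquely-named chromosomes."""

    def __init__(self, chromosomes: Sequence[Chromosome], assembly_label: str = ""):
        if not chromosomes:
            raise GenomeError("genome must contain at least one chromosome")
        seen = set()
        for c in chromosomes:
            if not c.id:
                raise GenomeError("chromosome id must be non-empty")
            if c.id in seen:
                raise GenomeError(f"duplicate chromosome id {c.id}")
            seen.add(c.id)
        self.chromosomes: tuple[Chromosome, ...] = tuple(chromosomes)
        self.assembly_label = assembly_label
        self._by_id = {c.id: c for c in self.chromosomes}

    def chromosome(self, chrom_id: str) -> Chromosome:
        try:
            return self._by_id[chrom_id]
        except KeyError:
            raise GenomeError(f"unknown chromosome id {chrom_id!r}") from None

    def __contains__(self, chrom_id: str) -> bool:
        return chrom_id in self._by_id

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def digest(self) -> str:
        """SHA-256 over ids and sequences; stable for identical content."""
        h = hashlib.sha256()
        for c in self.chromosomes:
            h.update(c.id.encode())
            h.update(b"\x00")
            h.update(c.seq.encode())
            h.update(b"\x00")
        return h.hexdigest()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.chromosomes == other.chromosomes

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Genome({len(self.chromosomes)} chromosomes, "
            f"{self.total_length} bp, label={self.assembly_label!r})"
        )


@dataclass(frozen=True)
class GenomicLocus:
    """(chromosome, strand, 1-based leftmost forward start, length).

    ``start`` always names the leftmost forward-strand base of the
    interval, regardless of strand; the interval covers forward
    positions start..start+length-1 inclusive.
    """

    chrom: str
    strand: Strand
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise LocusError(f"locus start must be >= 1, got {self.start}")
        if self.length < 1:
            raise LocusError(f"locus length must be >= 1, got {self.length}")

    @property
    def end(self) -> int:
        """1-based rightmost forward coordinate (inclusive)."""
        return self.start + self.length - 1

    def grown(self, left: int = 0, right: int = 0) -> "GenomicLocus":
        """Interval extended by ``left``/``right`` forward bases."""
        return replace(self, start=self.start - left, length=self.length + left + right)


def _check_record(rec_id: str, seq: str) -> None:
    bad = set(seq) - GENOME_BASES
    if bad:
        ch = sorted(bad)[0]
        pos = seq.index(ch) + 1
        raise GenomeError(
            f"illegal character {ch!r} in record {rec_id!r} at sequence position {pos}"
        )


def load_genome(source: Union[str, Path, TextIO], assembly_label: str = "") -> Genome:
    """Load a multi-record FASTA into a :class:`Genome`.

    Record id = header token before the first whitespace; wrapped
    sequence lines are concatenated; lower-case (soft-masked) bases are
    upper-cased. Characters outside {A,C,G,T,N} are rejected.
    """
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
        if not assembly_label:
            assembly_label = Path(source).name
    else:
        handle, close = source, False
    try:
        chroms: list[Chromosome] = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            _check_record(rec.id, seq)
            chroms.append(Chromosome(rec.id, seq))
    finally:
        if close:
            handle.close()
    if not chroms:
        raise GenomeError("empty FASTA: no records found")
    return Genome(chroms, assembly_label=assembly_label)


def write_fasta(genome: Genome, dest: Union[str, Path, TextIO], width: int = 60) -> None:
    """Write a genome back to multi-record FASTA with wrapped lines."""
    if isinstance(dest, (str, Path)):
        handle: TextIO = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        for c in genome.chromosomes:
            handle.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                handle.write(c.seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def _bounds_check(genome: Genome, loc: GenomicLocus) -> Chromosome:
    chrom = genome.chromosome(loc.chrom)
    if loc.end > chrom.length:
        raise LocusError(
            f"locus {loc.chrom}:{loc.start}-{loc.end} out of bounds "
            f"(chromosome length {chrom.length})"
        )
    return chrom


def locus_sequence(genome: Genome, loc: GenomicLocus) -> str:
    """Sequence of a locus, read 5'->3' along its own strand.

    Plus strand: the forward bases start..end. Minus strand: their
    reverse complement. The addressed interval must be N-free.
    """
    chrom = _bounds_check(genome, loc)
    sub = chrom.seq[loc.start - 1 : loc.end]
    if "N" in sub:
        raise LocusError(f"ambiguous base in locus {loc.chrom}:{loc.start}-{loc.end}")
    return sub if loc.strand is Strand.PLUS else revcomp(sub)


def flank_base(genome: Genome, loc: GenomicLocus, side: Side) -> Union[str, FlankSignal]:
    """The genomic base adjacent to a locus, in the motif's own frame.

    For a plus-strand locus the 3' flank is the forward base at
    start+length and the 5' flank the forward base at start-1. For a
    minus-strand locus the roles swap and the base is complemented (the
    motif reads right-to-left along the forward sequence).

    Returns the single base, or :class:`FlankSignal` when the required
    forward coordinate falls outside the chromosome (BOUNDARY) or the
    base there is N (AMBIGUOUS).
    """
    chrom = _bounds_check(genome, loc)
    if loc.strand is Strand.PLUS:
        pos = loc.end + 1 if side is Side.THREE_PRIME else loc.start - 1
    else:
        pos = loc.start - 1 if side is Side.THREE_PRIME else loc.end + 1
    if pos < 1 or pos > chrom.length:
        return FlankSignal.BOUNDARY
    base = chrom.seq[pos - 1]
    if base == "N":
        return FlankSignal.AMBIGUOUS
    return base if loc.strand is Strand.PLUS else complement(base)


# ---------------------------------------------------------------------------
# Tabular interchange: TSV locus lists and BED6 export
# ---------------------------------------------------------------------------

LOCUS_TABLE_COLUMNS = ["chrom", "strand", "start_1based", "length"]


def read_locus_table(source: Union[str, Path, TextIO]) -> list[GenomicLocus]:
    """Read a TSV of loci (columns chrom, strand, start_1based, length)."""
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    missing = [c for c in LOCUS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"locus table missing columns: {missing}")
    return [
        GenomicLocus(
            chrom=str(row.chrom),
            strand=Strand.from_symbol(row.strand),
            start=int(row.start_1based),
            length=int(row.length),
        )
        for row in df.itertuples()
    ]


def write_locus_table(loci: Iterable[GenomicLocus], dest: Union[str, Path, TextIO]) -> None:
    df = pd.DataFrame(
        [(l.chrom, l.strand.value, l.start, l.length) for l in loci],
        columns=LOCUS_TABLE_COLUMNS,
    )
    df.to_csv(dest, sep="\t", index=False)


def loci_to_bed6(loci: Iterable[GenomicLocus], names: Iterable[str] | None = None) -> str:
    """Render loci as BED6 text (0-based half-open, strand in column 6)."""
    out = io.StringIO()
    names = list(names) if names is not None else None
    for i, loc in enumerate(loci):
        name = names[i] if names else f"locus{i + 1}"
        out.write(
            f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{name}\t0\t{loc.strand.value}\n"
        )
    return out.getvalue()
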