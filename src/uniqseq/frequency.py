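"""Exact, mismatch-free occurrence counting and position listing.

The frequency counter answers one question: how many times does a motif
occur, exactly and with no mismatch at any position, on each strand of
each chromosome? Minus-strand occurrences are the forward-sequence
occurrences of the motif's reverse complement, reported by their
leftmost forward coordinate, so that the motif itself reads 5'->3'
along the minus strand at each reported site.

Semantics pinned by tests:

* overlapping occurrences count (``AA`` occurs 3x in ``AAAA``);
* a palindromic motif at one site counts once per strand (total 2);
* windows containing N never match (an exact matcher cannot assert
  equality to an undetermined base);
* "unique" downstream means total = 1 summed over both strands of the
  whole genome.

Two interchangeable index structures are provided behind
:func:`build_index`: the exhaustive scanner (the small-genome default)
and a k-mer table that prefilters candidate positions. Their answers
are identical by contract.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .core import Strand, revcomp, validate_motif
from .genome import Genome, GenomeError

__all__ = [
    "FrequencyReport",
    "PositionList",
    "OccurrenceIndex",
    "ScanIndex",
    "KmerIndex",
    "build_index",
    "find_all",
]


def find_all(text: str, pattern: str) -> Iterator[int]:
    """Yield 0-based start positions of every (overlapping) occurrence."""
    if not pattern:
        return
    i = text.find(pattern)
    while i != -1:
        yield i
        i = text.find(pattern, i + 1)


@dataclass(frozen=True)
class FrequencyReport:
    """Per-(chromosome, strand) exact-match counts plus the genome total."""

    motif: str
    per_cell: dict[tuple[str, Strand], int]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "total", sum(self.per_cell.values()))

    def count(self, chrom: str, strand: Strand) -> int:
        return self.per_cell[(chrom, strand)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (chrom, strand) cell, zeros included."""
        rows = [
            {"chrom": c, "strand": s.value, "count": n}
            for (c, s), n in self.per_cell.items()
        ]
        return pd.DataFrame(rows, columns=["chrom", "strand", "count"])

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "total": self.total,
            "cells": [
                {"chrom": c, "strand": s.value, "count": n}
                for (c, s), n in self.per_cell.items()
            ],
        }


@dataclass(frozen=True)
class PositionList:
    """Ascending 1-based leftmost forward coordinates of exact hits."""

    motif: str
    chrom: str
    strand: Strand
    starts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValueError("starts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.starts)

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "chrom": self.chrom,
            "strand": self.strand.value,
            "starts": list(self.starts),
        }


class OccurrenceIndex:
    """Query interface over one genome; subclasses differ only in speed.

    The contract — pinned by the naive-scan oracle in the test suite —
    is that ``count_occurrences`` and ``locate`` agree exactly with a
    position-by-position sliding-window comparison.
    """

    def __init__(self, genome: Genome):
        self.genome = genome

    # subclasses implement: 0-based forward hits of a plain pattern
    def _forward_hits(self, chrom_id: str, pattern: str) -> list[int]:
        raise NotImplementedError

    def _strand_pattern(self, motif: str, strand: Strand) -> str:
        return motif if strand is Strand.PLUS else revcomp(motif)

    def count_occurrences(self, motif: str) -> FrequencyReport:
        """Exact genome-wide counts of a motif on both strands.

        A motif longer than every chromosome simply yields total 0.
        """
        m = validate_motif(motif)
        per_cell: dict[tuple[str, Strand], int] = {}
        for chrom in self.genome:
            for strand in (Strand.PLUS, Strand.MINUS):
                per_cell[(chrom.id, strand)] = len(
                    self._forward_hits(chrom.id, self._strand_pattern(m, strand))
                )
        return FrequencyReport(motif=m, per_cell=per_cell)

    def locate(self, motif: str, chrom_id: str, strand: Strand) -> PositionList:
        """All hit positions of a motif on one (chromosome, strand)."""
        m = validate_motif(motif)
        if chrom_id not in self.genome:
            raise GenomeError(f"unknown chromosome id {chrom_id!r}")
        hits = self._forward_hits(chrom_id, self._strand_pattern(m, strand))
        return PositionList(
            motif=m, chrom=chrom_id, strand=strand, starts=tuple(p + 1 for p in hits)
        )


class ScanIndex(OccurrenceIndex):
    """Exhaustive scan over the raw sequence — the default and the
    structure-free reference. No preprocessing, O(genome) per query."""

    def _forward_hits(self, chrom_id: str, pattern: str) -> list[int]:
        return list(find_all(self.genome.chromosome(chrom_id).seq, pattern))


class KmerIndex(OccurrenceIndex):
    """k-mer position table used to prefilter candidate sites.

    Motifs of length >= k look up their first k-mer and verify each
    candidate; shorter motifs fall back to the exhaustive scan. k-mers
    containing N are never entered in the table, which preserves the
    no-match-through-N rule.
    """

    def __init__(self, genome: Genome, k: int = 8):
        super().__init__(genome)
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._tables: dict[str, dict[str, list[int]]] = {}
        for chrom in genome:
            table: dict[str, list[int]] = defaultdict(list)
            seq = chrom.seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    table[kmer].append(i)
            self._tables[chrom.id] = dict(table)

    def _forward_hits(self, chrom_id: str, pattern: str) -> list[int]:
        seq = self.genome.chromosome(chrom_id).seq
        if len(pattern) < self.k:
            return list(find_all(seq, pattern))
        candidates = self._tables[chrom_id].get(pattern[: self.k], ())
        return [p for p in candidates if seq.startswith(pattern, p)]


def build_index(genome: Genome, structure: str = "scan", k: int = 8) -> OccurrenceIndex:
    """Build an occurrence index.

    Parameters
    ----------
    structure
        ``"scan"`` (exhaustive scanner, the default) or ``"kmer"``.
    k
        k-mer size for the ``"kmer"`` structure; ignored otherwise.

    Whatever the structure, query answers are identical.
    """
    if structure == "scan":
        return ScanIndex(genome)
    if structure == "kmer":
        return KmerIndex(genome, k=k)
    raise ValueError(f"unknown index structure {structure!r}")
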