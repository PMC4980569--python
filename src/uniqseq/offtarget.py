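"""Closest-sequence (off-target) reporting for unique motifs.

Once a motif of length n is unique genome-wide, its closest relatives —
the n-1 and n-2 motifs obtained by trimming one or two bases off the
terminal end — necessarily occur at more than one site, and those sites
are the most likely off-target binding positions for any reagent
designed against the unique motif. Only terminal trims are considered:
an internal mismatch would be a different motif altogether.

The trim end follows the growth end: a 5'->3' extension is undone at
the 3' end, a 3'->5' extension at the 5' end. A bidirectional extension
never visited an n-1 state, so both single-end trims are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import MotifError, Strand, validate_motif
from .frequency import FrequencyReport, OccurrenceIndex, PositionList
from .genome import Side
from .extender import Direction, ExtensionResult, ExtensionStatus

__all__ = [
    "ClosestEntry",
    "ClosestSequenceReport",
    "closest_sequences",
    "closest_from_extension",
]


@dataclass(frozen=True)
class ClosestEntry:
    """One trimmed motif with its genome-wide frequency and positions."""

    k: int  # trimmed length (n-1 or n-2)
    motif: str
    frequency: FrequencyReport
    positions: tuple[PositionList, ...] | None = None  # non-empty cells only

    def to_dict(self) -> dict:
        d = {"k": self.k, "motif": self.motif, "frequency": self.frequency.to_dict()}
        if self.positions is not None:
            d["positions"] = [p.to_dict() for p in self.positions]
        return d


@dataclass(frozen=True)
class ClosestSequenceReport:
    """The n-1 and n-2 terminal trims of a unique motif."""

    unique_motif: str
    trim_end: Side
    entries: tuple[ClosestEntry, ...]

    def entry(self, k: int) -> ClosestEntry:
        for e in self.entries:
            if e.k == k:
                return e
        raise KeyError(k)

    def to_dict(self) -> dict:
        return {
            "unique_motif": self.unique_motif,
            "trim_end": self.trim_end.value,
            "entries": [e.to_dict() for e in self.entries],
        }


def _trim(motif: str, end: Side, drop: int) -> str:
    # motif strings are written 5'->3', so the 3' end is the right end
    return motif[:-drop] if end is Side.THREE_PRIME else motif[drop:]


def _positions_of(idx: OccurrenceIndex, motif: str) -> tuple[PositionList, ...]:
    lists = []
    for chrom in idx.genome:
        for strand in (Strand.PLUS, Strand.MINUS):
            pl = idx.locate(motif, chrom.id, strand)
            if pl.starts:
                lists.append(pl)
    return tuple(lists)


def closest_sequences(
    idx: OccurrenceIndex,
    unique_motif: str,
    trim_end: Side,
    with_positions: bool = True,
) -> ClosestSequenceReport:
    """Frequency (and optionally all positions) of the n-1 and n-2 trims.

    The motif must be at least 3 nt so both trims are non-empty.
    """
    m = validate_motif(unique_motif)
    if len(m) < 3:
        raise MotifError("motif too short for n-2 trim")
    entries = []
    for drop in (1, 2):
        trimmed = _trim(m, trim_end, drop)
        entries.append(
            ClosestEntry(
                k=len(trimmed),
                motif=trimmed,
                frequency=idx.count_occurrences(trimmed),
                positions=_positions_of(idx, trimmed) if with_positions else None,
            )
        )
    return ClosestSequenceReport(unique_motif=m, trim_end=trim_end, entries=tuple(entries))


def closest_from_extension(
    idx: OccurrenceIndex,
    res: ExtensionResult,
    with_positions: bool = True,
) -> list[ClosestSequenceReport]:
    """Closest-sequence report(s) for a unique extension result.

    The trim end is inferred from the growth direction (3' for 5'->3'
    growth, 5' for 3'->5'); bidirectional results yield two reports, one
    per end. For unidirectional growth the n-1 entry's total equals the
    penultimate trace frequency — the trim literally undoes the last
    extension step.
    """
    if res.status is not ExtensionStatus.UNIQUE:
        raise ValueError(
            f"closest-sequence search needs a unique result, got {res.status.value!r}"
        )
    if res.direction is Direction.FIVE_TO_THREE:
        ends = [Side.THREE_PRIME]
    elif res.direction is Direction.THREE_TO_FIVE:
        ends = [Side.FIVE_PRIME]
    else:
        ends = [Side.THREE_PRIME, Side.FIVE_PRIME]
    return [
        closest_sequences(idx, res.final_sequence, end, with_positions=with_positions)
        for end in ends
    ]
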