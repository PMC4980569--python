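"""Iterative motif extension to genome-wide uniqueness.

The extender grows a genomic motif one adjacent genomic base per step
(two for bidirectional growth: one at each end), recounting the exact
genome-wide frequency of the grown sequence after every step, and stops
as soon as the frequency reaches 1 — the sequence then occurs at exactly
one site across both strands of the whole genome.

Growth is defined in the motif's own 5'->3' frame: "5'->3'" appends the
genomic base just past the motif's 3' end, "3'->5'" prepends the base
just before its 5' end. For a minus-strand locus these map to the
opposite forward-coordinate directions; :func:`uniqseq.genome.flank_base`
owns that mapping.

Extension runs in two stages. Stage 1 caps the total sequence length at
30 nt — short unique sequences are the useful ones for sequence-directed
reagent design. When a motif sits inside a long duplication it cannot
become unique within that cap; stage 2 resumes from where stage 1
stopped under a much larger deterministic length cap (default 10 000).

Because each step's sequence contains the previous step's sequence, the
recorded frequency trace is non-increasing, and it is always >= 1 (every
evaluated sequence is read from the genome at its own locus).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

from .genome import (
    FlankSignal,
    Genome,
    GenomicLocus,
    Side,
    flank_base,
    locus_sequence,
)
from .frequency import OccurrenceIndex

__all__ = [
    "Direction",
    "ExtensionStatus",
    "ExtensionStep",
    "ExtenderConfig",
    "ExtensionResult",
    "extend_to_unique",
    "extend_all_directions",
    "stage2_continue",
]


class Direction(str, Enum):
    """Growth direction in the motif's own 5'->3' reading frame."""

    FIVE_TO_THREE = "5to3"
    THREE_TO_FIVE = "3to5"
    BIDIRECTIONAL = "both"


class ExtensionStatus(str, Enum):
    UNIQUE = "unique"
    CAP_EXCEEDED = "cap_exceeded"
    BOUNDARY_BLOCKED = "boundary_blocked"
    AMBIGUOUS_BASE = "ambiguous_base"


class ExtensionStep(NamedTuple):
    """One evaluated sequence: its length and genome-wide total."""

    length: int
    frequency: int


@dataclass(frozen=True)
class ExtenderConfig:
    """Length caps for the two extension stages.

    stage1_cap
        Total-length cap for stage 1 (default 30 nt). An input already
        longer than the cap is evaluated as-is and, if non-unique,
        reports cap_exceeded without growing.
    stage2_cap
        Deterministic total-length cap for stage 2 (default 10 000 nt),
        replacing any wall-clock stop: reproducibility requires a
        length-based rule.
    """

    stage1_cap: int = 30
    stage2_cap: int = 10_000

    def __post_init__(self) -> None:
        if not (1 <= self.stage1_cap <= self.stage2_cap):
            raise ValueError("require 1 <= stage1_cap <= stage2_cap")

    def cap(self, stage: str) -> int:
        if stage == "stage1":
            return self.stage1_cap
        if stage == "stage2":
            return self.stage2_cap
        raise ValueError(f"unknown stage {stage!r}")


@dataclass(frozen=True)
class ExtensionResult:
    """Outcome of one extension run.

    ``trace`` records every evaluated sequence, first entry = the input
    motif; ``final_sequence`` always equals the sequence of
    ``final_locus`` and contains the input motif (as prefix for 5'->3'
    growth, suffix for 3'->5', infix for bidirectional).
    """

    input_locus: GenomicLocus
    direction: Direction
    status: ExtensionStatus
    final_sequence: str
    final_locus: GenomicLocus
    trace: tuple[ExtensionStep, ...]
    stage: str = "stage1"

    @property
    def final_frequency(self) -> int:
        return self.trace[-1].frequency

    @property
    def final_length(self) -> int:
        return len(self.final_sequence)

    def to_dict(self) -> dict:
        return {
            "input_locus": _locus_dict(self.input_locus),
            "direction": self.direction.value,
            "status": self.status.value,
            "stage": self.stage,
            "final_sequence": self.final_sequence,
            "final_length": self.final_length,
            "final_locus": _locus_dict(self.final_locus),
            "trace": [[s.length, s.frequency] for s in self.trace],
        }


def _locus_dict(loc: GenomicLocus) -> dict:
    return {
        "chrom": loc.chrom,
        "strand": loc.strand.value,
        "start_1based": loc.start,
        "length": loc.length,
    }


_SIGNAL_STATUS = {
    FlankSignal.BOUNDARY: ExtensionStatus.BOUNDARY_BLOCKED,
    FlankSignal.AMBIGUOUS: ExtensionStatus.AMBIGUOUS_BASE,
}


def _grow(
    genome: Genome, loc: GenomicLocus, seq: str, direction: Direction
) -> tuple[GenomicLocus, str] | FlankSignal:
    """One growth step: fetch flank base(s), return grown locus+sequence.

    For bidirectional growth both ends are fetched before growing; if
    either end signals, the whole step fails with that signal (no silent
    fallback to one-sided growth).
    """
    if direction is Direction.FIVE_TO_THREE:
        b = flank_base(genome, loc, Side.THREE_PRIME)
        if isinstance(b, FlankSignal):
            return b
        left, right = (0, 1) if loc.strand.value == "+" else (1, 0)
        return loc.grown(left=left, right=right), seq + b
    if direction is Direction.THREE_TO_FIVE:
        b = flank_base(genome, loc, Side.FIVE_PRIME)
        if isinstance(b, FlankSignal):
            return b
        left, right = (1, 0) if loc.strand.value == "+" else (0, 1)
        return loc.grown(left=left, right=right), b + seq
    # bidirectional: two bases per iteration, one at each end
    b5 = flank_base(genome, loc, Side.FIVE_PRIME)
    if isinstance(b5, FlankSignal):
        return b5
    b3 = flank_base(genome, loc, Side.THREE_PRIME)
    if isinstance(b3, FlankSignal):
        return b3
    return loc.grown(left=1, right=1), b5 + seq + b3


def extend_to_unique(
    idx: OccurrenceIndex,
    genome: Genome,
    loc: GenomicLocus,
    direction: Direction,
    cfg: ExtenderConfig | None = None,
    stage: str = "stage1",
) -> ExtensionResult:
    """Grow the motif at ``loc`` until it is unique genome-wide.

    Stops with status ``unique`` when the grown sequence's both-strand
    genome-wide total reaches 1; ``cap_exceeded`` when the next growth
    step would exceed the active stage's length cap; or
    ``boundary_blocked`` / ``ambiguous_base`` when the needed flanking
    base runs off the chromosome or is N.
    """
    cfg = cfg or ExtenderConfig()
    seq = locus_sequence(genome, loc)
    freq = idx.count_occurrences(seq).total
    trace = [ExtensionStep(len(seq), freq)]
    return _run(idx, genome, loc, loc, seq, trace, direction, cfg, stage)


def _run(
    idx: OccurrenceIndex,
    genome: Genome,
    input_locus: GenomicLocus,
    cur: GenomicLocus,
    seq: str,
    trace: list[ExtensionStep],
    direction: Direction,
    cfg: ExtenderConfig,
    stage: str,
) -> ExtensionResult:
    cap = cfg.cap(stage)
    step_inc = 2 if direction is Direction.BIDIRECTIONAL else 1
    status: ExtensionStatus
    while True:
        if trace[-1].frequency == 1:
            status = ExtensionStatus.UNIQUE
            break
        if len(seq) + step_inc > cap:
            status = ExtensionStatus.CAP_EXCEEDED
            break
        grown = _grow(genome, cur, seq, direction)
        if isinstance(grown, FlankSignal):
            status = _SIGNAL_STATUS[grown]
            break
        cur, seq = grown
        trace.append(ExtensionStep(len(seq), idx.count_occurrences(seq).total))
    return ExtensionResult(
        input_locus=input_locus,
        direction=direction,
        status=status,
        final_sequence=seq,
        final_locus=cur,
        trace=tuple(trace),
        stage=stage,
    )


def extend_all_directions(
    idx: OccurrenceIndex,
    genome: Genome,
    loc: GenomicLocus,
    cfg: ExtenderConfig | None = None,
) -> dict[Direction, ExtensionResult]:
    """Stage-1 extension in all three directions, reported together so
    the caller can compare the outcomes and pick the best."""
    return {
        d: extend_to_unique(idx, genome, loc, d, cfg=cfg, stage="stage1")
        for d in Direction
    }


def stage2_continue(
    idx: OccurrenceIndex,
    genome: Genome,
    prior: ExtensionResult,
    cfg: ExtenderConfig | None = None,
) -> ExtensionResult:
    """Resume a cap-exceeded stage-1 run under the stage-2 length cap.

    Growth restarts from ``prior.final_locus`` in ``prior.direction``;
    the returned trace is the full history (stage 1 steps included).
    """
    if prior.status is not ExtensionStatus.CAP_EXCEEDED:
        raise ValueError(
            f"stage 2 requires a cap_exceeded result, got status {prior.status.value!r}"
        )
    cfg = cfg or ExtenderConfig()
    return _run(
        idx,
        genome,
        prior.input_locus,
        prior.final_locus,
        prior.final_sequence,
        list(prior.trace),
        prior.direction,
        cfg,
        "stage2",
    )


# ---------------------------------------------------------------------------
# Plain-text result cache (optional; used by the CLI)
# ---------------------------------------------------------------------------

def result_cache_key(
    genome_digest: str, loc: GenomicLocus, direction: Direction, cfg: ExtenderConfig, stage: str
) -> str:
    """Stable key for caching extension results as plain JSON files."""
    import hashlib

    raw = (
        f"{genome_digest}|{loc.chrom}|{loc.strand.value}|{loc.start}|{loc.length}"
        f"|{direction.value}|{cfg.stage1_cap}|{cfg.stage2_cap}|{stage}"
    )
    return hashlib.sha256(raw.encode()).hexdigest()
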