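"""Independent brute-force matcher used as the test oracle.

Two implementations of the naive sliding-window scan, both independent
of the package's str.find / k-mer query paths:

* ``positions_slow`` — per-position slice comparison, used on tiny
  genomes where O(L*n) Python is affordable;
* ``positions_fast`` — overlapping regex lookahead, used at 100 kb
  scale. The two agree with each other (checked in the suite).
"""

from __future__ import annotations

import re

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def positions_slow(text: str, pattern: str) -> list[int]:
    """0-based starts of every overlapping exact occurrence."""
    n = len(pattern)
    return [i for i in range(len(text) - n + 1) if text[i : i + n] == pattern]


def positions_fast(text: str, pattern: str) -> list[int]:
    return [m.start() for m in re.finditer(f"(?={re.escape(pattern)})", text)]


def oracle_cells(chrom_seqs: dict[str, str], motif: str, fast: bool = True):
    """Per-(chrom, strand symbol) counts plus total, naive semantics.

    Minus-strand hits are forward occurrences of the reverse complement,
    keyed by leftmost forward coordinate (1-based).
    """
    pos = positions_fast if fast else positions_slow
    cells: dict[tuple[str, str], list[int]] = {}
    for cid, seq in chrom_seqs.items():
        cells[(cid, "+")] = [p + 1 for p in pos(seq, motif)]
        cells[(cid, "-")] = [p + 1 for p in pos(seq, rc(motif))]
    counts = {k: len(v) for k, v in cells.items()}
    return cells, counts, sum(counts.values())


def oracle_total(chrom_seqs: dict[str, str], motif: str, fast: bool = True) -> int:
    return oracle_cells(chrom_seqs, motif, fast=fast)[2]
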