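# Methods

## Model and definitions

A *genome* is an ordered set of chromosomes over {A, C, G, T, N}. A
*motif* is a query string over {A, C, G, T}, always stored upper-case; a
*locus* is (chromosome, strand, 1-based leftmost forward start, length).
Matching is exact and mismatch-free: the occurrence count of motif *m* on
(chromosome *c*, plus strand) is the number of (possibly overlapping)
forward positions where *m* matches character-for-character; on the minus
strand it is the number of forward positions where revcomp(*m*) matches,
so that *m* itself reads 5′→3′ along the minus strand at each reported
site. Positions are always reported as leftmost forward coordinates.
*Uniqueness* means the total over both strands of all chromosomes equals 1.

Three consequences are worth keeping in mind:

* **Palindromes.** A motif equal to its own reverse complement matches at
  the same loci on both strands, so its total is always even and it can
  never be unique. `is_palindromic` flags such queries; extension from a
  palindromic core still works because the first asymmetric added base
  breaks the symmetry.
* **N.** Undetermined bases are legal in genomes but never match anything:
  an exact matcher cannot assert equality to an unknown base. N inside a
  query locus is an error; N encountered during extension terminates the
  run with `ambiguous_base`.
* **Overlaps.** Overlapping occurrences count. This is the natural
  exhaustive-search semantics and gives the testable closed form: the
  k-mer A^k occurs L−k+1 times on the plus strand of A^L.

## Extension procedure

Given a locus and a direction, the extender reads the input motif from the
genome, counts it genome-wide, then repeats: fetch the adjacent genomic
base at the growth end(s) in the motif's own 5′→3′ frame, grow the
sequence and its locus, recount. Stopping rules, in order of precedence:

* frequency = 1 → `unique` (an input that is already unique returns
  immediately with a length-1 trace);
* the next growth step would exceed the active length cap →
  `cap_exceeded` (an input already over the cap and non-unique reports
  this without growing);
* the required flanking base falls off the chromosome → `boundary_blocked`;
* the flanking base is N → `ambiguous_base`.

Unidirectional growth adds one base per step; bidirectional growth adds
one base at *each* end before recounting (two per iteration), so the final
length satisfies n = n₀ + 2·(steps). If either end of a bidirectional step
is blocked, the whole extension stops with that status rather than
silently degrading to one-sided growth.

Minus-strand loci are addressed by leftmost forward coordinate plus a
strand flag, and their sequence is read 5′→3′ along the minus strand.
3′ growth of a minus-strand motif therefore extends the forward interval
*leftward* (start−1) and appends the complement of the forward base at
start−1. This convention is pinned by tests that re-read every grown locus
and require it to reproduce the grown sequence exactly.

Invariants maintained and tested: the trace is non-increasing and every
entry ≥ 1; `final_sequence` equals the sequence of `final_locus`; the
final locus covers the input locus; a `unique` result is certified by an
independent recount (total 1, located exactly at the final locus).

### Two stages

Stage 1 caps total sequence length at 30 nt (default, configurable):
short unique sequences are the practically useful targets, and most motifs
outside long duplications resolve well within this bound. Stage 2 resumes
a `cap_exceeded` result from its final locus in the same direction under a
larger cap, default 10 000 nt. Both caps are deterministic lengths; a
wall-clock stop would make results irreproducible. The stage-2 trace
continues the stage-1 trace, so trace invariants hold across the join.

## Closest-sequence (off-target) search

For a unique motif of length n, the n−1 and n−2 motifs obtained by
trimming the terminal end are the closest sequences at which off-target
binding is expected; each is reported with its full per-chromosome,
per-strand frequency table and (optionally) every position. The trim end
follows the growth end — trimming undoes the most recent extension steps,
so for unidirectional growth the n−1 and n−2 totals equal the last-but-one
and last-but-two trace frequencies (a tested consistency). A bidirectional
result never visited an n−1 state, so both single-end trims are reported,
each independently meaningful as an off-target candidate. Motifs shorter
than 3 nt are rejected (the n−2 trim would be empty).

## Occurrence index

`build_index` returns one of two interchangeable structures: the
exhaustive scanner (`scan`, the default — no preprocessing, a C-speed
substring scan per query) or a k-mer position table (`kmer`, default
k = 8) that prefilters candidate sites by the motif's first k-mer and
verifies each. Their answers are identical by contract, and both are
checked exactly against a naive per-position sliding-window oracle in the
test suite (implemented twice, as a pure slice-comparison loop and as an
overlapping regex scan, both independent of the library's query paths).
At the genome sizes this package targets (≤ a few Mb) the scanner is
entirely adequate; frequency recounting during extension recounts fresh
each step.

## Synthetic genomes

The generator emulates exactly the structure the algorithms are sensitive
to, at desk scale:

* **Background**: i.i.d. bases given a GC fraction (default 0.41, the
  human-like value; realized GC is within ±0.02 on chromosomes ≥ 50 kb).
  There is no higher-order composition model and no repeat-family
  (Alu/LINE) simulation — passing tests demonstrate correctness of the
  exact-match logic, not performance on the repeat structure of real
  genomes, where unique lengths will generally be larger.
* **Plants**: each directive places `copies` copies of a core motif on the
  plus strand at non-overlapping random positions (rejection sampling;
  infeasible specs raise). Flank policies: `distinct_random_flanks`
  (fresh random flanks per copy, default 10 nt — copies are
  distinguishable a few bases out), `shared_flank(L)` (all copies share
  one flank pair — indistinguishable for L bases), and
  `duplicate_region(L)` (all copies paste one identical region with the
  core at its centre — forces stage-2 extension for L−offset > 30).
* **N-runs**: explicit intervals overwritten with N, protected from
  plants.
* **Self-verification**: after building, every recorded locus is re-read
  and must equal its core, and the exhaustive scanner must count at least
  `copies` genome-wide occurrences of each core (the exact total is
  recorded in the ground truth). Downstream tests treat the ground truth
  as authoritative because the generator has already proved it.

Generation is fully deterministic per seed (one `numpy` Generator,
consumed in a fixed order).

`table1_style_fixture(seed)` bundles an application-scale survey: a
2 × 50 kb genome with 20 distinct decameric cores planted 4× each under
distinct random flanks, plus one core planted inside two identical 200-nt
duplicated regions. One copy per ordinary core is designated the query
target, and the builder verifies the fixture's guarantees — every
designated target extends 5′→3′ to a unique sequence ≤ 30 nt, and the
duplicated core does not — retrying deterministically derived sub-seeds
until they hold. The duplicated core is deliberately not a designated
target: it exists to exercise stage 2, which the two-stage tests do via
the ground truth. With the core centred at offset 95 of a 200-nt
duplication, growth leaves the duplication at length 106, and stage 2
resolves exactly at the first length the brute-force scan certifies as
unique (106 unless the background happens to continue the match).

## Numerical and design choices

* Coordinates: 1-based fully closed everywhere in the library and TSV
  output (columns are labelled `start_1based`); BED6 export is 0-based
  half-open. This double convention is confined to the I/O layer.
* Queries are rejected, not coerced: N and IUPAC degenerate codes have no
  defined semantics under exact matching. Genome and query case is folded
  so FASTA soft-masking cannot affect results.
* Problem sizes in the test suite and acceptance script (100 kb genomes,
  200–1000 random motifs, 20-target surveys) were chosen as the smallest
  scale at which every phenomenon of interest — multi-copy cores,
  background hits of short motifs, duplication-forced stage 2 — occurs
  robustly; all complete in seconds.
* The extender's per-step recount is a fresh index query; an incremental
  hit-narrowing scheme (each step's hit set is a subset of the previous
  one) would be equivalent and faster at chromosome scale but is
  unnecessary at the scales targeted here.
* Extension results are cacheable as plain JSON keyed by (genome digest,
  locus, direction, caps, stage); the CLI exposes this via `--cache`.
* CLI exit codes: 0 unique, 3 cap exceeded, 4 blocked (boundary/N),
  5 motif absent from the genome.

## Known limitations

* Whole-genome (GRCh37/38) runs are supported in principle — the loader
  holds genomes in memory and the scanner is linear — but published
  frequencies for human motifs are assembly-dependent; the optional
  `scripts/validate_full_genome.py` recounts them against a user-supplied,
  explicitly labelled assembly.
* No mismatch-tolerant or PWM search: off-target analysis is restricted to
  terminal trims by design.
* Polymorphism is out of scope: uniqueness is relative to the reference
  sequence provided, and a variant at the locus can break it.
* Minus-strand position output follows this package's declared convention
  (leftmost forward coordinate); other tools may report minus-strand hits
  differently.
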