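# uniqseq

Unique-sequence prediction for DNA motifs: exact genome-wide occurrence
counting on both strands, position listing, iterative extension of a motif
with its own genomic flanking bases until it occurs exactly once in the
genome, and enumeration of the closest off-target sites.

## The problem

A transcription factor's binding motif — say the decameric p53 response
element — is typically repeated thousands of times across a genome. Any
sequence-directed reagent (a minor-groove binder, a polyamide, an anchored
primer, a guide) designed against the bare motif will therefore bind at
thousands of unintended sites. The core motif, however, sits in different
flanking sequence at every locus. Anchoring on the core and extending into
the flanks yields, usually within a few extra bases, a sequence that is
**unique**: its exact-match count across both strands of the whole genome
equals 1.

`uniqseq` automates this search as four chained steps:

1. **Frequency counting** — exact, mismatch-free occurrence counts of a
   motif *m* per chromosome and strand. Minus-strand occurrences are the
   forward-sequence occurrences of the reverse complement
   (so *m* reads 5′→3′ along the minus strand at each reported site);
   overlapping occurrences count; windows containing N never match.
2. **Position finding** — 1-based leftmost forward coordinates of every hit
   on a chosen (chromosome, strand).
3. **Extension** — starting from a genomic locus (chrom, strand, start,
   length), grow the sequence by the adjacent genomic base at its 3′ end
   (5′→3′), its 5′ end (3′→5′), or both ends at once (bidirectional),
   recounting the genome-wide total *f* after each step, until *f* = 1.
   Because each grown sequence contains the previous one, the trace
   *f₀ ≥ f₁ ≥ … ≥ 1* is non-increasing. Stage 1 caps the total length at
   30 nt; motifs inside long duplications cannot resolve there and can be
   continued in stage 2 under a larger deterministic length cap (default
   10 000 nt).
4. **Closest-sequence (off-target) search** — once a sequence of length *n*
   is unique, its terminal trims of length *n*−1 and *n*−2 necessarily
   occur at additional sites; their frequencies and positions are the
   most likely off-target binding sites. Only terminal trims are
   considered — an internal mismatch is a different motif altogether.

A seeded synthetic-genome generator (`uniqseq.synthetic`) plants motif
cores at controlled copy numbers inside controlled flanks — including
identical duplicated regions that force stage-2 extension — and records
ground-truth loci, so every algorithm can be validated end to end without
a multi-gigabyte genome download.

## Worked example

A 12-base genome with `chr1 = ATGCAAATGCTT`:

```sh
$ uniqseq count --genome demo.fa --motif ATGC
chrom   strand  count
chr1    +       2
chr1    -       0
TOTAL   *       2
```

`ATGC` occurs twice (forward positions 1 and 7); it is not unique. Extend
the occurrence at position 1 in the 5′→3′ direction:

```sh
$ uniqseq extend --genome demo.fa --chrom chr1 --strand + --start 1 \
      --length 4 --direction 5to3
{ "status": "unique",
  "final_sequence": "ATGCA",
  "final_length": 5,
  "final_locus": {"chrom": "chr1", "strand": "+", "start_1based": 1, "length": 5},
  "trace": [[4, 2], [5, 1]] }
```

One added base suffices: `ATGCA` (length 5) occurs once genome-wide — the
trace shows the frequency falling from 2 to 1. The exit status is 0 for a
unique result (3 = length cap exceeded, 4 = blocked by a chromosome end or
an N). The closest off-target sites are the 3′ trims of the unique motif:

```sh
$ uniqseq closest --genome demo.fa --motif ATGCA --trim-end 3p
k       motif   chrom   strand  count
4       ATGC    chr1    +       2
4       ATGC    TOTAL   *       2
3       ATG     chr1    +       2
3       ATG     TOTAL   *       2
```

Both the *n*−1 motif (`ATGC`) and the *n*−2 motif (`ATG`) occur twice — a
reagent built against `ATGCA` should be counter-screened at those sites.

`uniqseq pipeline --genome demo.fa --motif ATGC --pick-first` chains all
four steps (count → locate → extend in all three directions → closest) and
writes one JSON bundle in which each stage's input is the previous stage's
output. `uniqseq simulate` generates synthetic genomes from a JSON spec or
the bundled `--preset table1` multi-motif fixture.

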