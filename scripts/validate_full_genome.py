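#!/usr/bin/env python
"""Optional full-genome validation against published p53-motif frequencies.

The genome-wide frequencies previously reported for the original web
service were computed on a human assembly whose exact version (GRCh37
vs GRCh38) was not pinned, so exact agreement is assembly-dependent.
This script recounts each published decameric p53 response-element
motif on a user-supplied human genome FASTA and prints the measured
frequency next to the published one, labelled with the assembly you
name:

    python scripts/validate_full_genome.py \
        --genome /path/to/GRCh38.fa --assembly GRCh38 [--out report.tsv]

Not run in CI: it needs a multi-gigabyte local FASTA and tens of
minutes of scanning.
"""

from __future__ import annotations

import argparse
import sys

import pandas as pd

from uniqseq import build_index, load_genome

# Published genome-wide frequencies of decameric p53 binding motifs
# (original web-service results on an unpinned human assembly).
PUBLISHED = [
    ("ATM", "AGACATGCTC", 2552),
    ("BCL2", "ATCTGTACAG", 3048),
    ("BRCA1", "TAGACATGTC", 1852),
    ("BRCA2", "AGGGATGCCC", 15627),
    ("COL18A1", "AGGCAGGCCC", 23085),
    ("DCC-II", "AGACATGTCT", 3868),
    ("ERBB2", "AGCCATGCCT", 4142),
    ("ESR1", "GGTCATGCCT", 2745),
    ("IGF1R", "GGACACGCCC", 599),
    ("KIT", "AGACATGGCC", 2981),
    ("MDM2", "CTGACTTGTCT", 937),
    ("MET", "AGACATGCCT", 4901),
    ("NF2", "AGGCATGCGC", 12392),
    ("NME1-I", "AGACTGGGCTGGGCATGGT", 1),
    ("NRAS", "AGGGCATGCC", 1980),
    ("PGR", "GAGGCATTTC", 3700),
    ("PHB", "TGGGGATGCC", 3011),
    ("TGFA-I", "GAGACATGCC", 2134),
    ("TSG101", "AAGGCATGTA", 3140),
]


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genome", required=True, help="human genome FASTA")
    ap.add_argument("--assembly", required=True, help="assembly label, e.g. GRCh38")
    ap.add_argument("--out", default=None, help="optional TSV report path")
    args = ap.parse_args()

    print(f"loading {args.genome} ...", file=sys.stderr)
    genome = load_genome(args.genome, assembly_label=args.assembly)
    idx = build_index(genome)
    rows = []
    for gene, motif, published in PUBLISHED:
        measured = idx.count_occurrences(motif).total
        rows.append({
            "gene": gene, "motif": motif, "assembly": args.assembly,
            "published_frequency": published, "measured_frequency": measured,
            "ratio": round(measured / published, 3) if published else None,
        })
        print(f"{gene:10s} {motif:22s} published={published:6d} "
              f"measured={measured:6d}", file=sys.stderr)
    df = pd.DataFrame(rows)
    text = df.to_csv(sep="\t", index=False)
    if args.out:
        with open(args.out, "w") as fh:
            fh.write(text)
    else:
        print(text)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
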