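import numpy as np
import pytest

from uniqseq import (
    Chromosome,
    Direction,
    ExtenderConfig,
    ExtensionStatus,
    Genome,
    GenomicLocus,
    Strand,
    build_index,
    extend_all_directions,
    extend_to_unique,
    locus_sequence,
    stage2_continue,
)
from uniqseq.synthetic import (
    DuplicateRegion,
    PlantDirective,
    SyntheticGenomeSpec,
    generate,
)

from conftest import chrom_seqs
from naive_oracle import oracle_total


class TestWorkedExample:
    def test_five_to_three_reaches_unique_in_one_step(self, worked_genome, worked_index):
        loc = GenomicLocus("chr1", Strand.PLUS, 1, 4)
        res = extend_to_unique(worked_index, worked_genome, loc, Direction.FIVE_TO_THREE)
        assert res.status is ExtensionStatus.UNIQUE
        assert res.final_sequence == "ATGCA"
        assert [tuple(s) for s in res.trace] == [(4, 2), (5, 1)]
        assert res.final_locus == GenomicLocus("chr1", Strand.PLUS, 1, 5)

    def test_already_unique_input_returns_unchanged(self, worked_genome, worked_index):
        loc = GenomicLocus("chr1", Strand.PLUS, 4, 5)  # "CAAAT", occurs once
        for d in Direction:
            res = extend_to_unique(worked_index, worked_genome, loc, d)
            assert res.status is ExtensionStatus.UNIQUE
            assert res.final_sequence == locus_sequence(worked_genome, loc)
            assert len(res.trace) == 1
            assert res.final_locus == loc

    def test_chromosome_end_blocks_growth(self):
        # "GCAA" occurs at 3 and 9; from 9, the 3' flank would sit at 13
        g = Genome([Chromosome("chr1", "ATGCAAATGCAA")])
        idx = build_index(g)
        loc = GenomicLocus("chr1", Strand.PLUS, 9, 4)
        res = extend_to_unique(idx, g, loc, Direction.FIVE_TO_THREE)
        assert res.status is ExtensionStatus.BOUNDARY_BLOCKED
        assert res.final_sequence == "GCAA"
        assert len(res.trace) == 1

    def test_n_flank_stops_with_ambiguous_base(self):
        g = Genome([Chromosome("chr1", "ACGTNACGTA")])
        idx = build_index(g)
        loc = GenomicLocus("chr1", Strand.PLUS, 1, 4)  # "ACGT", freq 4
        res = extend_to_unique(idx, g, loc, Direction.FIVE_TO_THREE)
        assert res.status is ExtensionStatus.AMBIGUOUS_BASE


class TestResultInvariants:
    def _all_fixture_results(self, table1):
        genome, truth, _, idx = table1
        for copy in truth.designated_targets():
            yield genome, extend_all_directions(idx, genome, copy.locus)

    def test_trace_monotone_selfmatch_and_containment(self, table1):
        for genome, results in self._all_fixture_results(table1):
            for d, res in results.items():
                freqs = [s.frequency for s in res.trace]
                assert all(f >= 1 for f in freqs)
                assert all(a >= b for a, b in zip(freqs, freqs[1:]))
                assert locus_sequence(genome, res.final_locus) == res.final_sequence
                inp = locus_sequence(genome, res.input_locus)
                if d is Direction.FIVE_TO_THREE:
                    assert res.final_sequence.startswith(inp)
                elif d is Direction.THREE_TO_FIVE:
                    assert res.final_sequence.endswith(inp)
                else:
                    assert inp in res.final_sequence
                # locus always covers the input locus
                assert res.final_locus.start <= res.input_locus.start
                assert res.final_locus.end >= res.input_locus.end

    def test_unique_status_iff_last_frequency_one(self, table1):
        for _, results in self._all_fixture_results(table1):
            for res in results.values():
                assert (res.status is ExtensionStatus.UNIQUE) == (
                    res.trace[-1].frequency == 1
                )

    def test_uniqueness_certificate_via_independent_recount(self, table1):
        genome, truth, _, idx = table1
        seqs = chrom_seqs(genome)
        for copy in truth.designated_targets()[:5]:
            res = extend_to_unique(idx, genome, copy.locus, Direction.FIVE_TO_THREE)
            assert res.status is ExtensionStatus.UNIQUE
            assert oracle_total(seqs, res.final_sequence) == 1
            pl = idx.locate(res.final_sequence, res.final_locus.chrom, res.final_locus.strand)
            assert pl.starts == (res.final_locus.start,)

    def test_bidirectional_parity(self, table1):
        genome, truth, _, idx = table1
        for copy in truth.designated_targets()[:5]:
            res = extend_to_unique(idx, genome, copy.locus, Direction.BIDIRECTIONAL)
            assert res.final_length == copy.locus.length + 2 * (len(res.trace) - 1)

    def test_growth_steps_add_one_or_two_bases(self, table1):
        for _, results in self._all_fixture_results(table1):
            for d, res in results.items():
                inc = 2 if d is Direction.BIDIRECTIONAL else 1
                lengths = [s.length for s in res.trace]
                assert all(b - a == inc for a, b in zip(lengths, lengths[1:]))


class TestMinusStrand:
    def test_minus_strand_growth_follows_motif_frame(self, synth100k):
        genome, truth, idx = synth100k
        plus = truth.copies[0].locus
        minus = GenomicLocus(plus.chrom, Strand.MINUS, plus.start, plus.length)
        res = extend_to_unique(idx, genome, minus, Direction.FIVE_TO_THREE)
        # 3' growth of a minus-strand motif extends the forward interval leftward
        assert res.final_locus.end == minus.end
        assert res.final_locus.start <= minus.start
        assert locus_sequence(genome, res.final_locus) == res.final_sequence


class TestCaps:
    def test_over_length_nonunique_input_reports_cap_exceeded_immediately(self):
        g = Genome([Chromosome("chr1", "ACGTACGTAC" * 4)])
        idx = build_index(g)
        loc = GenomicLocus("chr1", Strand.PLUS, 1, 8)  # repeated 8-mer
        cfg = ExtenderConfig(stage1_cap=6, stage2_cap=6)
        res = extend_to_unique(idx, g, loc, Direction.FIVE_TO_THREE, cfg)
        assert res.status is ExtensionStatus.CAP_EXCEEDED
        assert len(res.trace) == 1

    def test_invalid_caps_rejected(self):
        with pytest.raises(ValueError):
            ExtenderConfig(stage1_cap=0)
        with pytest.raises(ValueError):
            ExtenderConfig(stage1_cap=50, stage2_cap=30)


@pytest.fixture(scope="module")
def dup_fixture():
    spec = SyntheticGenomeSpec(
        seed=41,
        chromosomes=(("chr1", 40_000), ("chr2", 40_000)),
        gc_fraction=0.41,
        plants=(PlantDirective("TACGGATCCA", 2, DuplicateRegion(200)),),
    )
    genome, truth = generate(spec)
    return genome, truth, build_index(genome)


class TestTwoStage:
    def test_duplicated_region_needs_stage_two(self, dup_fixture):
        genome, truth, idx = dup_fixture
        copy = truth.copies[0]
        res1 = extend_to_unique(idx, genome, copy.locus, Direction.FIVE_TO_THREE)
        assert res1.status is ExtensionStatus.CAP_EXCEEDED
        assert res1.final_length == 30

        res2 = stage2_continue(idx, genome, res1)
        assert res2.status is ExtensionStatus.UNIQUE
        # cannot become unique while the growing sequence stays inside
        # the duplicated region
        core_offset = copy.locus.start - copy.region_start  # 0-based in region
        assert res2.final_length > 200 - core_offset
        # ground truth: the first greedy-path length at which the oracle
        # count drops to 1
        seqs = chrom_seqs(genome)
        chrom_seq = genome.chromosome(copy.locus.chrom).seq
        start0 = copy.locus.start - 1
        expected = None
        for L in range(copy.locus.length, 400):
            if oracle_total(seqs, chrom_seq[start0 : start0 + L]) == 1:
                expected = L
                break
        assert res2.final_length == expected
        # stage-2 trace continues the stage-1 trace
        assert res2.trace[: len(res1.trace)] == res1.trace

    def test_stage2_on_non_cap_result_rejected(self, worked_genome, worked_index):
        res = extend_to_unique(
            worked_index, worked_genome,
            GenomicLocus("chr1", Strand.PLUS, 1, 4), Direction.FIVE_TO_THREE,
        )
        assert res.status is ExtensionStatus.UNIQUE
        with pytest.raises(ValueError, match="cap_exceeded"):
            stage2_continue(worked_index, worked_genome, res)

    def test_duplication_longer_than_stage2_cap_caps_again(self, dup_fixture):
        genome, truth, idx = dup_fixture
        copy = truth.copies[0]
        cfg = ExtenderConfig(stage1_cap=30, stage2_cap=60)
        res1 = extend_to_unique(idx, genome, copy.locus, Direction.FIVE_TO_THREE, cfg)
        res2 = stage2_continue(idx, genome, res1, cfg)
        assert res2.status is ExtensionStatus.CAP_EXCEEDED
        assert res2.final_length == 60


class TestPlantedRecovery:
    def test_five_distinct_unique_extensions(self, synth100k):
        """Five copies with distinct random flanks -> five distinct unique
        sequences, each certified total 1 by the oracle."""
        genome, truth, idx = synth100k
        seqs = chrom_seqs(genome)
        finals = []
        for copy in truth.copies:
            res = extend_to_unique(idx, genome, copy.locus, Direction.FIVE_TO_THREE)
            assert res.status is ExtensionStatus.UNIQUE
            assert res.final_length <= 30
            assert oracle_total(seqs, res.final_sequence) == 1
            finals.append(res.final_sequence)
        assert len(set(finals)) == 5


def test_direction_asymmetry_with_shared_left_flank():
    """A motif whose left flank is duplicated but right flank is unique
    resolves faster growing 5'->3' than 3'->5'."""
    rng = np.random.default_rng(17)
    bases = list("ACGT")
    core = "GATTACAGCA"
    left = "".join(rng.choice(bases, size=40))
    bg = "".join(rng.choice(bases, size=20_000))
    r1 = "".join(rng.choice(bases, size=40))
    r2 = "".join(rng.choice(bases, size=40))
    seq = bg[:5000] + left + core + r1 + bg[5000:10000] + left + core + r2 + bg[10000:]
    g = Genome([Chromosome("chr1", seq)])
    idx = build_index(g)
    start = 5000 + 40 + 1
    loc = GenomicLocus("chr1", Strand.PLUS, start, len(core))
    assert locus_sequence(g, loc) == core
    res = extend_all_directions(idx, g, loc)
    r53 = res[Direction.FIVE_TO_THREE]
    r35 = res[Direction.THREE_TO_FIVE]
    assert r53.status is ExtensionStatus.UNIQUE
    if r35.status is ExtensionStatus.UNIQUE:
        assert r53.final_length < r35.final_length
    else:
        assert r35.status is ExtensionStatus.CAP_EXCEEDED
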