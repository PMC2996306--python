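import numpy as np
import pytest

from contigforge.assembler import (
    AssemblyPlan,
    assemble,
    assign_unused_reads,
    build_graph,
    canonical,
    extract_unitigs,
    iterative_assemble,
    revcomp,
)
from contigforge.io_formats import QualRead
from contigforge.synthetic_data import SimConfig, gen_reads, gen_transcriptome


def tile(seq, read_len=30, stride=3):
    """Error-free reads tiling a sequence, both ends included."""
    starts = list(range(0, len(seq) - read_len + 1, stride))
    if starts[-1] != len(seq) - read_len:
        starts.append(len(seq) - read_len)
    # double every start so a coverage floor of 2 is met everywhere
    reads = []
    for i, s in enumerate(starts):
        for d in (0, 1):
            reads.append(QualRead(f"r{i}_{d}", seq[s : s + read_len], [40] * read_len))
    return reads


@pytest.fixture
def source_seq(rng):
    return "".join(rng.choice(list("ACGT"), size=60))


class TestBuildGraph:
    def test_linear_path_node_count(self, source_seq):
        graph = build_graph(tile(source_seq), k=21, min_kmer_coverage=1)
        expect = {canonical(source_seq[i : i + 21]) for i in range(40)}
        assert set(graph.coverage) == expect
        assert len(graph) == 40

    def test_disjoint_sequences_make_two_components(self):
        a = "ACGTACGTACGTACGTACGTACG"
        b = "TTTTTTTGGGGGGGCCCCCACAC"
        graph = build_graph(tile(a, 23, 1) + tile(b, 23, 1), k=21, min_kmer_coverage=1)
        comp_a = {canonical(a[i : i + 21]) for i in range(3)}
        comp_b = {canonical(b[i : i + 21]) for i in range(3)}
        assert set(graph.coverage) == comp_a | comp_b
        for km in comp_a:
            assert all(canonical(s) not in comp_b for s in graph.successors(km))

    def test_singleton_error_kmer_pruned(self, source_seq):
        err = source_seq[:20] + ("A" if source_seq[20] != "A" else "C") + source_seq[21:51]
        reads = tile(source_seq) + [QualRead("err", err[:30], [40] * 30)]
        graph = build_graph(reads, k=21, min_kmer_coverage=2)
        assert canonical(err[:21]) not in graph.coverage
        assert canonical(source_seq[:21]) in graph.coverage

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            build_graph([], k=20)

    def test_n_kmers_skipped(self):
        seq = "ACGTACGTACGTACGTACGTNACGTACGTACGTACGTACGT"
        graph = build_graph([QualRead("r", seq, [40] * len(seq))] * 2, k=21)
        assert all("N" not in km for km in graph.coverage)


class TestExtractUnitigs:
    def test_linear_graph_reconstructs_source(self, source_seq):
        graph = build_graph(tile(source_seq), k=21, min_kmer_coverage=1)
        (contig,) = extract_unitigs(graph)
        assert contig.seq in (source_seq, revcomp(source_seq))

    def test_shared_repeat_splits_into_five_unitigs(self, rng):
        flanks = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(4)]
        repeat = "".join(rng.choice(list("ACGT"), size=25))
        t1 = flanks[0] + repeat + flanks[1]
        t2 = flanks[2] + repeat + flanks[3]
        graph = build_graph(tile(t1, 25, 1) + tile(t2, 25, 1), k=21, min_kmer_coverage=1)
        unitigs = extract_unitigs(graph)
        assert len(unitigs) == 5
        # the repeat is one of them
        assert any(repeat in u.seq or revcomp(repeat) in u.seq for u in unitigs)

    def test_empty_graph(self):
        assert extract_unitigs(build_graph([], k=21)) == []

    def test_each_kmer_in_exactly_one_unitig(self, source_seq):
        graph = build_graph(tile(source_seq), k=21, min_kmer_coverage=1)
        unitigs = extract_unitigs(graph)
        seen = []
        for u in unitigs:
            for i in range(len(u.seq) - 20):
                seen.append(canonical(u.seq[i : i + 21]))
        assert sorted(seen) == sorted(graph.coverage)

    def test_deterministic_order(self, source_seq):
        reads = tile(source_seq)
        a = [u.seq for u in extract_unitigs(build_graph(reads, 21, 1))]
        b = [u.seq for u in extract_unitigs(build_graph(reads, 21, 1))]
        assert a == b


class TestUnusedReads:
    def test_contained_read_not_returned(self, source_seq):
        contigs = assemble(tile(source_seq), 21, 1)
        reads = [QualRead("in", source_seq[5:35], [40] * 30)]
        assert assign_unused_reads(reads, contigs, 21) == []

    def test_foreign_read_returned(self, source_seq, rng):
        contigs = assemble(tile(source_seq), 21, 1)
        other = "".join(rng.choice(list("ACGT"), size=30))
        reads = [QualRead("out", other, [40] * 30)]
        assert len(assign_unused_reads(reads, contigs, 21)) in (0, 1)
        # a read sharing no k-mer is always returned
        if not any(
            canonical(other[i : i + 21]) in {canonical(c.seq[j : j + 21]) for c in contigs for j in range(len(c.seq) - 20)}
            for i in range(10)
        ):
            assert assign_unused_reads(reads, contigs, 21) == reads

    def test_empty_contig_set_returns_all(self, source_seq):
        reads = tile(source_seq)
        assert assign_unused_reads(reads, [], 21) == reads


class TestIterativeAssembly:
    def make_reads(self, seed, n=3):
        cfg = SimConfig(seed=seed, n_transcripts=n, error_rate=0.0, split_fraction=0.0)
        rng = np.random.default_rng(seed)
        tx, _ = gen_transcriptome(cfg, rng)
        return tx, gen_reads(tx, cfg, rng)

    def test_exact_reconstruction_of_three_transcripts(self):
        tx, reads = self.make_reads(seed=11)
        contigs = iterative_assemble(reads)
        truth = {min(t.seq, revcomp(t.seq)) for t in tx}
        assert {c.seq for c in contigs} == truth

    def test_deterministic(self):
        _, reads = self.make_reads(seed=5, n=2)
        a = [c.seq for c in iterative_assemble(reads)]
        b = [c.seq for c in iterative_assemble(reads)]
        assert a == b

    def test_final_set_covers_every_exploratory_assembly(self):
        tx, reads = self.make_reads(seed=8, n=2)
        plan = AssemblyPlan()
        final = iterative_assemble(reads, plan)
        final_kmers = {
            canonical(c.seq[i : i + 21])
            for c in final
            for i in range(len(c.seq) - 20)
        }
        for k in plan.exploratory_ks:
            for contig in assemble(reads, k, plan.min_kmer_coverage):
                for i in range(len(contig.seq) - 20):
                    assert canonical(contig.seq[i : i + 21]) in final_kmers

    def test_low_coverage_transcript_rescued_by_small_k(self, rng):
        # 2x coverage: k=49 leaves gaps more often than k=21; the final set
        # must still contain every base the k=21 assembly recovered
        seq = "".join(rng.choice(list("ACGT"), size=400))
        reads = []
        for i, s in enumerate(range(0, 326, 36)):  # sparse 75-mers, ~2x
            reads.append(QualRead(f"a{i}", seq[s : s + 75], [40] * 75))
            reads.append(QualRead(f"b{i}", seq[s : s + 75], [40] * 75))
        final = iterative_assemble(reads)
        k21 = assemble(reads, 21, 2)
        final_bases = sum(len(c.seq) for c in final)
        assert final_bases >= max(len(c.seq) for c in k21)


class TestPlan:
    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            AssemblyPlan(final_k=40)

    def test_defaults_mirror_protocol(self):
        plan = AssemblyPlan()
        assert tuple(plan.exploratory_ks) == (21, 25, 31, 35, 41, 49, 59)
        assert plan.unused_read_k == 57 and plan.final_k == 39
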