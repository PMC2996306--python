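import numpy as np
import pytest

from contigforge.aligners import overlap_align, revcomp
from contigforge.assembler import Contig
from contigforge.io_formats import SeqRecord, TabularHit
from contigforge.target_clustering import (
    GroupMember,
    TargetGroup,
    dedupe_ests,
    est_cluster,
    est_group_refine,
    est_prefilter,
    join_to_est,
    norm_score_filter,
    peptide_cluster,
)


def hit(q, t, score, t_start=1, t_end=50, minus=False):
    return TabularHit(q, t, score, 1e-20, 1, 50, t_start, t_end, -1 if minus else 1, minus)


@pytest.fixture
def random_seq(rng):
    def make(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    return make


class TestDedupeEsts:
    def test_exact_duplicates_collapse(self, random_seq):
        s = random_seq(80)
        out = dedupe_ests([SeqRecord("a", s), SeqRecord("b", s)])
        assert [e.id for e in out] == ["a"]

    def test_substring_est_removed(self, random_seq):
        s = random_seq(120)
        out = dedupe_ests([SeqRecord("long", s), SeqRecord("short", s[20:90])])
        assert [e.id for e in out] == ["long"]

    def test_reverse_complement_containment_removed(self, random_seq):
        s = random_seq(120)
        out = dedupe_ests([SeqRecord("long", s), SeqRecord("rc", revcomp(s[10:80]))])
        assert [e.id for e in out] == ["long"]

    def test_disjoint_kept(self, random_seq):
        ests = [SeqRecord("a", random_seq(60)), SeqRecord("b", random_seq(60))]
        assert len(dedupe_ests(ests)) == 2


class TestEstPrefilter:
    def test_boundary_not_greater_than_drops(self):
        contig, est = SeqRecord("c", "A" * 100), SeqRecord("e", "A" * 150)
        aln_350 = type("A", (), {"raw_score": 350.0})()
        aln_351 = type("A", (), {"raw_score": 351.0})()
        assert not est_prefilter(contig, est, aln_350)
        assert est_prefilter(contig, est, aln_351)

    def test_perfect_30nt_match_passes(self, random_seq):
        s = random_seq(30)
        contig, est = SeqRecord("c", s), SeqRecord("e", s)
        aln = overlap_align(contig, est)
        assert aln.raw_score == 150.0
        assert est_prefilter(contig, est, aln)  # 150 > 50 + 90


class TestNormScoreFilter:
    def test_survivors_at_cutoff(self):
        g = TargetGroup("e1", "est", [
            GroupMember("a", 200.0), GroupMember("b", 140.0), GroupMember("c", 90.0),
        ])
        norm_score_filter(g)
        assert [m.contig_id for m in g.survivors] == ["a", "b"]
        assert g.survivors[1].norm_score == pytest.approx(0.7)

    def test_singleton_survives(self):
        g = TargetGroup("e1", "est", [GroupMember("a", 5.0)])
        norm_score_filter(g)
        assert len(g.survivors) == 1 and g.survivors[0].norm_score == 1.0

    def test_all_equal_all_survive(self):
        g = TargetGroup("e1", "est", [GroupMember(c, 50.0) for c in "abc"])
        norm_score_filter(g)
        assert len(g.survivors) == 3


class TestEstGroupRefine:
    def test_half_score_contig_eliminated(self, random_seq):
        est = SeqRecord("e", random_seq(400))
        full = SeqRecord("full", est.seq)
        half = SeqRecord("half", est.seq[:200])
        g = TargetGroup("e", "est", survivors=[GroupMember("full", 100), GroupMember("half", 60)])
        est_group_refine(g, {"full": full, "half": half}, est)
        assert [m.contig_id for m in g.survivors] == ["full"]

    def test_boundary_point_seven_kept(self, random_seq):
        est = SeqRecord("e", random_seq(1000))
        a = SeqRecord("a", est.seq)  # score 5000
        b = SeqRecord("b", est.seq[:700])  # score 3500 = 0.7 exactly
        g = TargetGroup("e", "est", survivors=[GroupMember("a", 100), GroupMember("b", 80)])
        est_group_refine(g, {"a": a, "b": b}, est)
        assert [m.contig_id for m in g.survivors] == ["a", "b"]

    def test_single_survivor_untouched(self):
        g = TargetGroup("e", "est", survivors=[GroupMember("a", 10)])
        assert est_group_refine(g, {}, SeqRecord("e", "ACGT")).survivors == g.survivors


class TestJoinToEst:
    def test_contig_equal_to_est_gives_est(self, random_seq):
        est = SeqRecord("e", random_seq(300))
        contigs = {"c": SeqRecord("c", est.seq)}
        contig, rec = join_to_est(est, [GroupMember("c", 100)], contigs)
        assert contig.seq == est.seq
        assert rec.rule == "est_extend" and rec.n_gap_len == 0

    def test_three_prime_extension(self, random_seq):
        t = random_seq(400)
        est = SeqRecord("e", t[:350])
        contigs = {"c": SeqRecord("c", t[100:400])}
        contig, _ = join_to_est(est, [GroupMember("c", 100)], contigs)
        assert len(contig.seq) == 350 + 50
        assert contig.seq == t

    def test_per_side_max_rule(self, random_seq):
        t = random_seq(500)
        est = SeqRecord("e", t[30:460])
        contigs = {
            "left": SeqRecord("left", t[0:300]),
            "right": SeqRecord("right", t[200:500]),
        }
        members = [GroupMember("left", 100), GroupMember("right", 95)]
        contig, _ = join_to_est(est, members, contigs)
        assert len(contig.seq) == 30 + 430 + 40
        assert contig.seq == t

    def test_minus_strand_survivor_oriented(self, random_seq):
        t = random_seq(400)
        est = SeqRecord("e", t[:350])
        contigs = {"c": SeqRecord("c", revcomp(t[100:400]))}
        contig, _ = join_to_est(est, [GroupMember("c", 100, minus=True)], contigs)
        assert contig.seq == t


class TestEstClusterEndToEnd:
    def test_split_transcript_rejoined(self, random_seq):
        t = random_seq(900)
        frags = [Contig("f1", t[:480]), Contig("f2", t[420:])]
        est = SeqRecord("est", t[100:800])
        out, recs = est_cluster(frags, [est])
        assert len(recs) == 1
        joined = out[0]
        assert joined.provenance == "est_joined"
        assert joined.seq == t
        assert t[:480] in joined.seq and t[420:] in joined.seq

    def test_unrelated_contig_passes_through(self, random_seq):
        t, other = random_seq(900), random_seq(300)
        frags = [Contig("f1", t[:480]), Contig("f2", t[420:]), Contig("x", other)]
        out, _ = est_cluster(frags, [SeqRecord("est", t[100:800])])
        passthrough = [c for c in out if c.provenance == "unchanged"]
        assert [c.id for c in passthrough] == ["x"]

    def test_consumption_is_exclusive(self, random_seq):
        t = random_seq(900)
        frags = [Contig("f1", t[:480]), Contig("f2", t[420:])]
        out, recs = est_cluster(frags, [SeqRecord("e1", t[100:800]), SeqRecord("e2", t[120:780])])
        all_sources = [s for r in recs for s, _, _ in r.parts]
        assert len(all_sources) == len(set(all_sources))


class TestPeptideCluster:
    def make_pair(self, rng, overlap=True):
        from contigforge.synthetic_data import SimConfig, gen_transcriptome

        cfg = SimConfig(seed=int(rng.integers(1 << 16)), n_transcripts=1, len_range=(900, 1200))
        tx, prots = gen_transcriptome(cfg, rng)
        t = tx[0].seq
        L = len(t)
        mid = L // 2 - (L // 2) % 3
        if overlap:
            f1, f2 = t[: mid + 60], t[mid - 60 :]
        else:
            f1, f2 = t[: mid - 45], t[mid + 45 :]
        return t, prots[0], Contig("f1", f1), Contig("f2", f2)

    def test_two_overlapping_survivors_merged(self, rng):
        t, prot, f1, f2 = self.make_pair(rng, overlap=True)
        ref = SeqRecord(prot.id, prot.seq, "protein")
        out, recs = peptide_cluster([f1, f2], [ref])
        assert len(recs) == 1 and recs[0].rule == "pep_overlap_merge"
        merged = out[0]
        assert merged.provenance == "peptide_joined"
        assert merged.seq == t

    def test_non_overlapping_pair_scaffolded(self, rng):
        t, prot, f1, f2 = self.make_pair(rng, overlap=False)
        ref = SeqRecord(prot.id, prot.seq, "protein")
        out, recs = peptide_cluster([f1, f2], [ref])
        assert len(recs) == 1 and recs[0].rule == "pep_n_scaffold"
        scaf = out[0]
        assert scaf.provenance == "n_scaffolded"
        assert "N" * recs[0].n_gap_len in scaf.seq
        # 3 nt of N per residue of HSP gap: the planted gap is 90 nt = 30 aa
        assert recs[0].n_gap_len == pytest.approx(90, abs=6)

    def test_no_sequence_lost_in_scaffold(self, rng):
        _, prot, f1, f2 = self.make_pair(rng, overlap=False)
        out, recs = peptide_cluster([f1, f2], [SeqRecord(prot.id, prot.seq, "protein")])
        scaf = out[0]
        non_n = len(scaf.seq) - scaf.seq.count("N")
        assert non_n == len(f1.seq) + len(f2.seq)

    def test_unmatched_contig_untouched(self, rng, random_seq):
        c = Contig("lonely", random_seq(300))
        out, recs = peptide_cluster([c], [SeqRecord("p", "M" + "K" * 99, "protein")])
        assert recs == [] and out[0].id == "lonely"
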