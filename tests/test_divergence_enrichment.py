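import math

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from contigforge.aligners import PairwiseAlignment, global_align
from contigforge.divergence_enrichment import (
    DivergenceRecord,
    assign_bin,
    bin_divergence,
    category_enrichment,
    group_compare,
    identity_filter,
    protein_divergence,
    tercile_cutoffs,
)
from contigforge.io_formats import SeqRecord
from contigforge.synthetic_data import SimConfig, gen_orthologs, gen_transcriptome

from .oracles import chi2_stat, mannwhitney_exact


def aln_of(a, b):
    return PairwiseAlignment("a", "b", a, b, 0.0, 0.0, 0.0)


def rec(p_diff, cid="c", cats=()):
    return DivergenceRecord(cid, "p", p_diff, math.sqrt(p_diff), 1 - p_diff,
                            categories=set(cats))


class TestProteinDivergence:
    def test_identical(self):
        p, d, ident = protein_divergence(aln_of("MKV", "MKV"))
        assert (p, d, ident) == (0.0, 0.0, 1.0)

    def test_quarter_different(self):
        p, d, _ = protein_divergence(aln_of("MKVLMKVL", "MKVLMKAA"))
        assert p == 0.25 and d == 0.5

    def test_all_different(self):
        p, d, _ = protein_divergence(aln_of("MK", "VW"))
        assert p == 1.0 and d == 1.0

    def test_gap_columns_count_as_differences(self):
        p, _, ident = protein_divergence(aln_of("MKV-", "MKVW"))
        assert p == 0.25
        assert ident == 1.0  # identity is over non-gap columns

    def test_gap_excluded_mode(self):
        p, _, _ = protein_divergence(aln_of("MKV-", "MKVW"), count_gaps=False)
        assert p == 0.0

    def test_dist_squared_equals_p_diff(self, rng):
        """Distance is the square root of the differing proportion, measured
        on real alignments of mutated proteins."""
        cfg = SimConfig(seed=2, n_transcripts=3)
        _, prots = gen_transcriptome(cfg, rng)
        refs, _ = gen_orthologs(prots, 0.15, rng)
        for prot, ref in zip(prots, refs):
            aln = global_align(prot, ref)
            p, d, _ = protein_divergence(aln)
            assert d**2 == pytest.approx(p, rel=1e-12)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            protein_divergence(aln_of("", ""))


class TestIdentityFilter:
    @pytest.mark.parametrize("identity,kept", [(0.29, False), (0.30, True), (1.0, True)])
    def test_boundary(self, identity, kept):
        r = DivergenceRecord("c", "p", 0.5, math.sqrt(0.5), identity)
        assert (r in identity_filter([r])) is kept


class TestBinning:
    def test_fixed_cutoffs(self):
        assert assign_bin(0.138, 0.058, 0.138) == "High"
        assert assign_bin(0.058, 0.058, 0.138) == "Low"
        assert assign_bin(0.1, 0.058, 0.138) == "Intermediate"

    def test_terciles_split_exactly_in_thirds(self, rng):
        values = rng.permutation(np.linspace(0.01, 0.5, 300))
        records = [rec(v, cid=f"c{i}") for i, v in enumerate(values)]
        records, (low, high) = bin_divergence(records, "empirical_terciles")
        counts = {b: sum(1 for r in records if r.bin == b) for b in ("Low", "Intermediate", "High")}
        assert counts == {"Low": 100, "Intermediate": 100, "High": 100}

    def test_binning_monotone_in_p_diff(self, rng):
        values = sorted(rng.random(90))
        records, (low, high) = bin_divergence([rec(v, cid=str(v)) for v in values], "empirical_terciles")
        order = {"Low": 0, "Intermediate": 1, "High": 2}
        bins = [order[r.bin] for r in records]
        assert bins == sorted(bins)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            tercile_cutoffs([0.1, 0.2])


class TestGroupCompare:
    def test_identical_multisets_give_half_u(self):
        a = [0.1, 0.2, 0.35, 0.4]
        u, p = group_compare(a, list(a))
        assert u == len(a) ** 2 / 2

    def test_separated_groups_exact_p(self):
        u, p = group_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.random(4))
        b = list(rng.random(5))
        u_impl, p_impl = group_compare(a, b)
        u_oracle, p_oracle = mannwhitney_exact(a, b)
        assert u_impl == u_oracle
        assert p_impl == pytest.approx(p_oracle, rel=1e-9)

    def test_exact_and_asymptotic_agree_at_moderate_n(self, rng):
        a = list(rng.normal(0, 1, 25))
        b = list(rng.normal(0.3, 1, 25))
        _, p_exact = group_compare(a, b, exact_max=10_000)
        _, p_asym = group_compare(a, b, exact_max=0)
        assert p_asym == pytest.approx(p_exact, rel=0.10)

    def test_shift_alternative_detected(self, rng):
        """1-SD shift at n=100 per group is essentially always significant."""
        detected = 0
        for _ in range(20):
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            _, p = group_compare(list(a), list(b))
            detected += p < 0.001
        assert detected == 20

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])


class TestCategoryEnrichment:
    def make_records(self, spec):
        """spec: {category: (n_low, n_int, n_high)}"""
        records = []
        i = 0
        for cat, (nl, ni, nh) in spec.items():
            for b, n in zip(("Low", "Intermediate", "High"), (nl, ni, nh)):
                for _ in range(n):
                    r = rec(0.05, cid=f"c{i}", cats=[cat])
                    r.bin = b
                    records.append(r)
                    i += 1
        return records

    def test_uniform_counts_not_significant(self):
        records = self.make_records({"cat": (10, 10, 10)})
        (res,) = category_enrichment(records, expected="thirds")
        assert res.chi2 == pytest.approx(0.0) and res.p == pytest.approx(1.0)
        assert not res.significant

    def test_extreme_category_chi2_value(self):
        records = self.make_records({"cat": (30, 0, 0)})
        (res,) = category_enrichment(records, expected="thirds")
        assert res.chi2 == pytest.approx(60.0) and res.df == 2
        assert res.direction == "Low:enriched"

    def test_small_category_excluded(self):
        records = self.make_records({"big": (10, 10, 10), "tiny": (14, 0, 0)})
        results = category_enrichment(records, expected="thirds")
        assert [r.category for r in results] == ["big"]

    def test_bonferroni_alpha(self):
        records = self.make_records({f"c{i}": (6, 5, 5) for i in range(4)})
        results = category_enrichment(records, expected="thirds", alpha_family=0.05)
        assert all(r.alpha == pytest.approx(0.05 / 4) for r in results)

    def test_multi_category_records_count_in_each(self):
        records = self.make_records({"a": (15, 0, 0)})
        for r in records:
            r.categories.add("b")
        results = category_enrichment(records, expected="thirds")
        assert {r.category for r in results} == {"a", "b"}

    @pytest.mark.parametrize("seed", range(5))
    def test_chi2_matches_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(60, [1 / 3] * 3)
        records = self.make_records({"cat": tuple(counts)})
        (res,) = category_enrichment(records, expected="thirds")
        assert res.chi2 == pytest.approx(chi2_stat(counts, [20, 20, 20]))
        assert res.p == pytest.approx(float(chi2_dist.sf(res.chi2, 2)))

    def test_null_type_one_error_rate(self, rng):
        """Under the multinomial null the chi-square test rejects at close
        to its nominal level."""
        n_sim, n = 4000, 60
        rejections = 0
        for counts in rng.multinomial(n, [1 / 3] * 3, size=n_sim):
            stat = chi2_stat(counts, [n / 3] * 3)
            rejections += chi2_dist.sf(stat, 2) < 0.05
        rate = rejections / n_sim
        assert abs(rate - 0.05) < 0.011
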