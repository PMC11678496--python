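import numpy as np
import pytest

from mixsense.concordance import (
    adjusted_quartiles,
    categorize_pairs,
    depth_histogram,
    gc_content,
    group_iqrs,
    mann_whitney,
    quartiles_iqr,
    reverse_complement,
    split_by_category,
    wilcoxon_matched,
)
from mixsense.pairs import InformativePair, MixtureObservation, PairType
from mixsense.vcf_io import VariantKey

from _oracles import oracle_categorize
from conftest import make_callset


def bare_pair(pos, ptype=PairType.N_HO, chrom="1"):
    return InformativePair(key=VariantKey(chrom, pos, "A", "G"), pair_type=ptype,
                           dna1=None, dna2=None, dna1_depth=None, dna2_depth=None)


class TestCategorize:
    def test_simple_partition(self):
        a = [bare_pair(1), bare_pair(2)]
        b = [bare_pair(2), bare_pair(3)]
        assignment = categorize_pairs(a, b)
        assert assignment.venn == (1, 1, 1)
        assert {k.pos for k, _ in assignment.common} == {2}

    def test_identical_sets_all_common(self):
        a = [bare_pair(i) for i in range(1, 6)]
        assignment = categorize_pairs(a, list(a))
        assert assignment.venn == (0, 5, 0)

    def test_pair_type_is_part_of_match_key(self):
        a = [bare_pair(1, PairType.N_HO)]
        b = [bare_pair(1, PairType.HO_N)]
        assert categorize_pairs(a, b).venn == (1, 0, 1)

    def test_swap_symmetry_and_oracle(self, rng):
        for _ in range(20):
            a = [bare_pair(int(p)) for p in rng.choice(100, size=30, replace=False) + 1]
            b = [bare_pair(int(p)) for p in rng.choice(100, size=30, replace=False) + 1]
            fwd = categorize_pairs(a, b)
            rev = categorize_pairs(b, a)
            assert fwd.venn == (rev.venn[2], rev.venn[1], rev.venn[0])
            a_only, common, b_only = oracle_categorize(a, b)
            assert (fwd.a_only, fwd.common, fwd.b_only) == (a_only, common, b_only)

    def test_split_by_category_views(self):
        a = [bare_pair(1), bare_pair(2)]
        b = [bare_pair(2)]
        assignment = categorize_pairs(a, b)
        split = split_by_category(a, assignment, "a")
        assert [p.key.pos for p in split["common"]] == [2]
        assert [p.key.pos for p in split["specific"]] == [1]


class FakeFasta(dict):
    """Mapping of contig name to string; supports slicing like pyfaidx."""


class TestGcContent:
    def test_extreme_windows(self):
        ref = FakeFasta({"1": "G" * 200, "2": "A" * 200})
        assert gc_content(ref, VariantKey("1", 100, "G", "A")) == 100.0
        assert gc_content(ref, VariantKey("2", 100, "A", "G")) == 0.0

    def test_exact_count(self):
        seq = "GC" * 18 + "G" + "AT" * 32  # 37 G/C then 64 A/T = 101 bp
        assert len(seq) == 101
        ref = FakeFasta({"1": seq})
        # window centered at pos 51 covers the whole contig
        assert gc_content(ref, VariantKey("1", 51, seq[50], "T" if seq[50] != "T" else "C")) \
            == pytest.approx(100 * 37 / 101)
        assert round(100 * 37 / 101, 2) == 36.63

    def test_strand_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=101))
        fwd = FakeFasta({"1": seq})
        rev = FakeFasta({"1": reverse_complement(seq)})
        key_fwd = VariantKey("1", 51, seq[50], "A" if seq[50] != "A" else "C")
        rc = reverse_complement(seq)[50]
        key_rev = VariantKey("1", 51, rc, "A" if rc != "A" else "C")
        assert gc_content(fwd, key_fwd) == pytest.approx(gc_content(rev, key_rev))

    def test_window_truncated_at_contig_edge(self):
        ref = FakeFasta({"1": "GCGCGCGCGC"})  # 10 bp, all G/C
        assert gc_content(ref, VariantKey("1", 2, "C", "T")) == 100.0

    def test_n_bases_excluded(self):
        ref = FakeFasta({"1": "N" * 40 + "GCGC" + "N" * 60})
        assert gc_content(ref, VariantKey("1", 42, "C", "T")) == 100.0
        all_n = FakeFasta({"1": "N" * 200})
        assert gc_content(all_n, VariantKey("1", 100, "A", "G")) is None

    def test_chr_prefix_match(self):
        ref = FakeFasta({"chr1": "G" * 200})
        assert gc_content(ref, VariantKey("1", 100, "G", "A")) == 100.0

    def test_missing_chrom(self):
        with pytest.raises(KeyError):
            gc_content(FakeFasta({"1": "ACGT"}), VariantKey("2", 1, "A", "G"))


class TestQuartiles:
    def test_type7_interpolation(self):
        summary = quartiles_iqr([1, 2, 3, 4])
        assert (summary.q1, summary.q3) == (1.75, 3.25)
        assert summary.iqr == pytest.approx(1.5)

    def test_constant_values(self):
        assert quartiles_iqr([0.5] * 10).iqr == 0.0

    def test_permutation_invariance(self, rng):
        values = list(rng.uniform(size=25))
        shuffled = list(values)
        rng.shuffle(shuffled)
        assert quartiles_iqr(values) == quartiles_iqr(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quartiles_iqr([])

    def test_adjusted_quartiles_are_display_only(self):
        summary = quartiles_iqr([0.1, 0.2, 0.3, 0.4, 0.5])
        adjusted = adjusted_quartiles(summary)
        assert adjusted.median == 0.5
        assert adjusted.iqr == pytest.approx(summary.iqr)


class TestWilcoxonMatched:
    def test_identical_inputs_give_p_one(self):
        assert wilcoxon_matched([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_seven_uniform_signs_exact_p(self):
        """All seven paired differences positive: two-sided exact p = 2/2^7."""
        a = [0.10, 0.12, 0.15, 0.18, 0.22, 0.30, 0.40]
        b = [x - 0.01 * (i + 1) for i, x in enumerate(a)]
        _, p = wilcoxon_matched(a, b)
        assert p == pytest.approx(2 / 2**7)
        assert p == pytest.approx(0.015625)

    def test_sign_flip_symmetry(self, rng):
        a = list(rng.uniform(size=9))
        b = list(rng.uniform(size=9))
        _, p_fwd = wilcoxon_matched(a, b)
        _, p_rev = wilcoxon_matched(b, a)
        assert p_fwd == pytest.approx(p_rev)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_matched([1, 2], [1, 2, 3])


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_disjoint_n3_exact_p(self):
        """x entirely below y at n=m=3: two-sided exact p = 2/C(6,3) = 0.1."""
        _, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_u_statistics_sum_to_nm(self, rng):
        x = list(rng.uniform(size=8))
        y = list(rng.uniform(size=11))
        u_xy, _ = mann_whitney(x, y)
        u_yx, _ = mann_whitney(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestDepthHistogram:
    def test_count_times_depth(self):
        cs = make_callset("S", [("1", i, "A", "G", 50, 0.5) for i in range(1, 4)])
        frame = depth_histogram(cs)
        row = frame[frame.depth == 50].iloc[0]
        assert (row.n_variants, row.total_reads) == (3, 150)

    def test_empty_callset(self):
        assert depth_histogram(make_callset("S", [])).empty

    def test_matches_brute_force(self, rng):
        depths = [int(d) for d in rng.integers(5, 40, size=60)]
        cs = make_callset("S", [("1", i + 1, "A", "G", d, 0.5) for i, d in enumerate(depths)])
        frame = depth_histogram(cs).set_index("depth")
        for d in set(depths):
            assert frame.loc[d, "n_variants"] == depths.count(d)
            assert frame.loc[d, "total_reads"] == depths.count(d) * d


class TestGroupIqrs:
    def test_groups_ordered_by_evaf(self):
        pairs = []
        for pos in range(1, 6):
            observations = tuple(
                MixtureObservation(sample_id=f"CH{int(100 * f)}", depth=50,
                                   vaf=min(1.0, max(0.0, 1 - f + 0.01 * pos)),
                                   evaf=1 - f, group_label=f"V{round(100 * (1 - f))}")
                for f in (0.05, 0.5, 0.95)
            )
            pairs.append(InformativePair(key=VariantKey("1", pos, "A", "G"),
                                         pair_type=PairType.N_HO, dna1=None, dna2=None,
                                         dna1_depth=None, dna2_depth=None,
                                         observations=observations))
        frame = group_iqrs(pairs)
        assert list(frame.group) == ["V5", "V50", "V95"]
        assert (frame.n == 5).all()
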