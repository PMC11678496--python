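import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixsense.errors import DesignError
from mixsense.pairs import (
    MixtureDesign,
    PairType,
    expected_vaf,
    group_label,
    select_nh_pairs,
    trim_pairs,
)

from _oracles import oracle_select, oracle_trim
from conftest import make_callset, make_depth_table, random_mixture_callsets, random_pure_callsets


class TestExpectedVaf:
    def test_ch10_inverse_relation(self):
        assert expected_vaf(PairType.N_HO, 0.10) == pytest.approx(0.90)
        assert expected_vaf(PairType.HO_N, 0.10) == pytest.approx(0.10)

    def test_pure_dna2_carries_nho_variant(self):
        assert expected_vaf(PairType.N_HO, 0.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_vaf(PairType.N_HO, 1.2)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_orientations_sum_to_one(self, f1):
        assert expected_vaf(PairType.N_HO, f1) + expected_vaf(PairType.HO_N, f1) == pytest.approx(1.0)


class TestDesign:
    def test_canonical_fractions(self, design):
        assert dict(design.samples)["CH10"] == 0.10
        assert design.sample_ids == ("CH5", "CH10", "CH20", "CH50", "CH80", "CH90", "CH95")

    @pytest.mark.parametrize("samples", [
        (("CH5", 0.05), ("CH5", 0.10)),      # duplicate id
        (("CH5", 0.0),),                      # f1 out of range
        (("CH10", 0.10), ("CH5", 0.05)),      # not sorted
        (("A", 0.1), ("B", 0.1)),             # duplicate fraction
    ])
    def test_invalid_designs_rejected(self, samples):
        with pytest.raises(DesignError):
            MixtureDesign(tuple(samples))

    def test_group_labels(self):
        assert group_label(0.05) == "V5"
        assert group_label(0.95) == "V95"
        assert group_label(0.5) == "V50"


class TestSelection:
    def test_definitional_nho_pair(self):
        dna1 = make_callset("DNA1", [])
        dna2 = make_callset("DNA2", [("1", 1000, "A", "G", 40, 1.0)])
        d1 = make_depth_table([("1", 1000, 30)])
        pairs = select_nh_pairs(dna1, dna2, d1, None)
        assert len(pairs) == 1
        assert pairs[0].pair_type is PairType.N_HO
        assert pairs[0].dna1_depth == 30

    def test_vaf_above_null_threshold_fails(self):
        dna1 = make_callset("DNA1", [("1", 1000, "A", "G", 50, 0.06)])
        dna2 = make_callset("DNA2", [("1", 1000, "A", "G", 50, 1.0)])
        assert select_nh_pairs(dna1, dna2, None, None) == []

    def test_vaf_exactly_at_null_threshold_is_null(self):
        dna1 = make_callset("DNA1", [("1", 1000, "A", "G", 50, 0.05)])
        dna2 = make_callset("DNA2", [("1", 1000, "A", "G", 50, 1.0)])
        assert len(select_nh_pairs(dna1, dna2, None, None)) == 1

    def test_low_depth_excluded(self):
        dna1 = make_callset("DNA1", [("1", 1000, "A", "G", 9, 1.0)])
        dna2 = make_callset("DNA2", [])
        d2 = make_depth_table([("1", 1000, 40)])
        assert select_nh_pairs(dna1, dna2, None, d2) == []

    def test_depth_exactly_at_minimum_kept(self):
        dna1 = make_callset("DNA1", [("1", 1000, "A", "G", 10, 1.0)])
        dna2 = make_callset("DNA2", [])
        d2 = make_depth_table([("1", 1000, 10)])
        assert len(select_nh_pairs(dna1, dna2, None, d2)) == 1

    def test_sex_chromosomes_excluded(self):
        dna2 = make_callset("DNA2", [("X", 1000, "A", "G", 40, 1.0),
                                     ("1", 1000, "A", "G", 40, 1.0)])
        pairs = select_nh_pairs(make_callset("DNA1", []), dna2,
                                make_depth_table([("X", 1000, 30), ("1", 1000, 30)]), None)
        assert [p.key.chrom for p in pairs] == ["1"]

    def test_hom_in_both_is_not_a_pair(self):
        dna1 = make_callset("DNA1", [("1", 1000, "A", "G", 50, 1.0)])
        dna2 = make_callset("DNA2", [("1", 1000, "A", "G", 50, 1.0)])
        assert select_nh_pairs(dna1, dna2, None, None) == []

    def test_other_allele_at_site_breaks_null(self):
        # DNA1 has a different hom alt at the site: it is not reference-only
        dna1 = make_callset("DNA1", [("1", 1000, "A", "T", 50, 1.0)])
        dna2 = make_callset("DNA2", [("1", 1000, "A", "G", 50, 1.0)])
        assert select_nh_pairs(dna1, dna2, None, None) == []

    def test_strict_mode_drops_unknown_depth(self):
        dna2 = make_callset("DNA2", [("1", 1000, "A", "G", 40, 1.0)])
        lenient = select_nh_pairs(make_callset("DNA1", []), dna2, None, None)
        strict = select_nh_pairs(make_callset("DNA1", []), dna2, None, None, strict=True)
        assert len(lenient) == 1 and strict == []


def _mixtures_for(pair_rows, design, overrides=None):
    """All-compliant mixture call sets for the given pair keys; ``overrides``
    maps sample_id -> (vaf, depth) replacing the default observation."""
    from mixsense.pairs import expected_vaf as evaf_of

    mixtures = {}
    for sid, f1 in design.samples:
        rows = []
        for chrom, pos, ref, alt, ptype in pair_rows:
            evaf = evaf_of(ptype, f1)
            vaf, depth = evaf, 50
            if overrides and sid in overrides:
                vaf, depth = overrides[sid]
            rows.append((chrom, pos, ref, alt, depth, vaf))
        mixtures[sid] = make_callset(sid, rows)
    return mixtures


class TestTrimming:
    PAIR = [("1", 1000, "A", "G", PairType.N_HO)]

    def _selected(self):
        dna1 = make_callset("DNA1", [])
        dna2 = make_callset("DNA2", [("1", 1000, "A", "G", 40, 1.0)])
        return select_nh_pairs(dna1, dna2, make_depth_table([("1", 1000, 30)]), None)

    def test_high_vaf_in_low_evaf_mixture_removed(self, design):
        mixtures = _mixtures_for(self.PAIR, design, {"CH90": (0.75, 50)})
        assert trim_pairs(self._selected(), mixtures, None, design) == []

    def test_ch50_below_limit_retained(self, design):
        mixtures = _mixtures_for(self.PAIR, design, {"CH50": (0.79, 50)})
        assert len(trim_pairs(self._selected(), mixtures, None, design)) == 1

    def test_ch50_at_limit_removed(self, design):
        mixtures = _mixtures_for(self.PAIR, design, {"CH50": (0.80, 50)})
        assert trim_pairs(self._selected(), mixtures, None, design) == []

    def test_low_depth_in_high_evaf_mixture_removed(self, design):
        # N-Ho: CH5 has eVAF 0.95, so depth 8 there trims the pair
        mixtures = _mixtures_for(self.PAIR, design, {"CH5": (0.95, 8)})
        assert trim_pairs(self._selected(), mixtures, None, design) == []

    def test_hon_low_depth_in_ch95_removed(self, design):
        dna1 = make_callset("DNA1", [("1", 1000, "A", "G", 40, 1.0)])
        selected = select_nh_pairs(dna1, make_callset("DNA2", []), None,
                                   make_depth_table([("1", 1000, 30)]))
        pair_rows = [("1", 1000, "A", "G", PairType.HO_N)]
        mixtures = _mixtures_for(pair_rows, design, {"CH95": (0.95, 8)})
        assert trim_pairs(selected, mixtures, None, design) == []

    def test_label_bijection_and_reversal(self, design):
        dna1 = make_callset("DNA1", [("1", 2000, "C", "T", 40, 1.0)])
        dna2 = make_callset("DNA2", [("1", 1000, "A", "G", 40, 1.0)])
        d1 = make_depth_table([("1", 1000, 30)])
        d2 = make_depth_table([("1", 2000, 30)])
        selected = select_nh_pairs(dna1, dna2, d1, d2)
        pair_rows = [("1", 1000, "A", "G", PairType.N_HO), ("1", 2000, "C", "T", PairType.HO_N)]
        mixtures = _mixtures_for(pair_rows, design)
        trimmed = trim_pairs(selected, mixtures, None, design)
        assert len(trimmed) == 2
        labels = {"V5", "V10", "V20", "V50", "V80", "V90", "V95"}
        for pair in trimmed:
            by_sample = {o.sample_id: o.group_label for o in pair.observations}
            assert set(by_sample.values()) == labels
        nho = next(p for p in trimmed if p.pair_type is PairType.N_HO)
        hon = next(p for p in trimmed if p.pair_type is PairType.HO_N)
        nho_labels = [o.group_label for o in nho.observations]
        hon_labels = [o.group_label for o in hon.observations]
        assert nho_labels == list(reversed(hon_labels))
        assert hon_labels == ["V5", "V10", "V20", "V50", "V80", "V90", "V95"]

    def test_trim_is_subset_and_idempotent(self, design, rng):
        dna1, dna2, d1, d2 = random_pure_callsets(rng, n_sites=150)
        selected = select_nh_pairs(dna1, dna2, d1, d2)
        mixtures, tables = random_mixture_callsets(rng, selected, design)
        once = trim_pairs(selected, mixtures, tables, design)
        keys = {(p.key, p.pair_type) for p in once}
        assert keys <= {(p.key, p.pair_type) for p in selected}
        twice = trim_pairs(once, mixtures, tables, design)
        assert [(p.key, p.pair_type) for p in twice] == [(p.key, p.pair_type) for p in once]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_select_and_trim_match_brute_force(self, seed, design):
        rng = np.random.default_rng(1000 + seed)
        dna1, dna2, d1, d2 = random_pure_callsets(rng, n_sites=150)
        selected = select_nh_pairs(dna1, dna2, d1, d2)
        got = {(p.key, p.pair_type.value) for p in selected}
        assert got == oracle_select(dna1, dna2, d1, d2)
        mixtures, tables = random_mixture_callsets(rng, selected, design)
        trimmed = trim_pairs(selected, mixtures, tables, design)
        got_trim = {(p.key, p.pair_type.value) for p in trimmed}
        assert got_trim == oracle_trim(got, mixtures, tables, design)
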