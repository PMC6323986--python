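"""Enrichment statistics: ORA, AFC, KS fallback, per-framework BH, routing."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netenrich as ne
from netenrich.errors import ConfigError, ValidationError

from conftest import bh_stepup_oracle


def gs(members, sid="S"):
    return ne.GeneSet(sid, "", frozenset(members))


class TestORA:
    def test_full_overlap_small_universe(self):
        # all 5 query genes hit a 5-member set in a 20-gene background:
        # p = 1 / C(20, 5)
        bg = {f"g{i:02d}" for i in range(20)}
        q = {f"g{i:02d}" for i in range(5)}
        r = ne.ora_hypergeometric(q, gs(q), bg)
        assert r.p_raw == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert r.n_members_in_input == 5

    def test_zero_overlap_p_is_one(self):
        bg = {f"g{i}" for i in range(20)}
        r = ne.ora_hypergeometric({"g0", "g1"}, gs({"g10", "g11"}), bg)
        assert r.p_raw == 1.0

    def test_set_equal_to_background_p_is_one(self):
        bg = {f"g{i}" for i in range(10)}
        r = ne.ora_hypergeometric({"g0", "g1"}, gs(bg), bg)
        assert r.p_raw == pytest.approx(1.0)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            ne.ora_hypergeometric({"zzz"}, gs({"g1"}), {"g1", "g2"})

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ne.ora_hypergeometric(set(), gs({"g1"}), {"g1"})
        with pytest.raises(ValidationError):
            ne.ora_hypergeometric({"g1"}, gs({"g1"}), set())


class TestAFCExhaustive:
    def test_top_pair_of_four(self, small_value_table):
        r = ne.afc_test(small_value_table, gs({"c", "d"}))
        assert r.statistic == pytest.approx(3.5)
        assert r.p_up == pytest.approx(1 / 6)
        assert r.direction == "up"

    def test_identical_values_p_one_both_tails(self):
        t = ne.GeneValueTable({f"g{i}": 2.0 for i in range(8)})
        r = ne.afc_test(t, gs({"g0", "g1"}))
        assert r.p_up == 1.0 and r.p_down == 1.0 and r.p_raw == 1.0

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(2)
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=9))}
        t = ne.GeneValueTable(vals)
        members = {"g0", "g3", "g7"}
        r = ne.afc_test(t, gs(members))
        arr = np.array([vals[g] for g in sorted(vals)])
        obs = np.mean([vals[g] for g in members])
        null = np.array([np.mean(c) for c in combinations(arr, 3)])
        assert r.p_up == pytest.approx(np.mean(null >= obs - 1e-12))
        assert r.p_down == pytest.approx(np.mean(null <= obs + 1e-12))

    def test_empty_intersection_skipped(self, small_value_table):
        assert ne.afc_test(small_value_table, gs({"zzz"})) is None


class TestAFCMonteCarlo:
    def test_same_seed_same_p(self):
        rng = np.random.default_rng(4)
        t = ne.GeneValueTable({f"g{i}": float(v) for i, v in enumerate(rng.normal(size=60))})
        s = gs({f"g{i}" for i in range(10)})
        r1 = ne.afc_test(t, s, n_perm=500, seed=42, exhaustive_limit=10)
        r2 = ne.afc_test(t, s, n_perm=500, seed=42, exhaustive_limit=10)
        assert (r1.p_up, r1.p_down) == (r2.p_up, r2.p_down)

    def test_seed_required_for_monte_carlo(self):
        t = ne.GeneValueTable({f"g{i}": float(i) for i in range(60)})
        with pytest.raises(ConfigError, match="seed"):
            ne.afc_test(t, gs({"g0", "g1"}), exhaustive_limit=10)

    def test_add_one_correction_bounds_p_away_from_zero(self):
        t = ne.GeneValueTable({f"g{i}": float(i) for i in range(60)})
        r = ne.afc_test(t, gs({"g58", "g59"}), n_perm=200, seed=1, exhaustive_limit=10)
        assert r.p_up >= 1 / 201

    def test_converges_to_exhaustive(self):
        # C(12, 3) = 220 subsets: exact p available; MC must approach it
        rng = np.random.default_rng(6)
        t = ne.GeneValueTable({f"g{i}": float(v) for i, v in enumerate(rng.normal(size=12))})
        s = gs({"g1", "g5", "g9"})
        exact = ne.afc_test(t, s)
        mc = ne.afc_test(t, s, n_perm=100_000, seed=3, exhaustive_limit=10)
        assert abs(mc.p_up - exact.p_up) < 0.01
        assert abs(mc.p_down - exact.p_down) < 0.01

    def test_shift_invariance_of_p(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=40)
        t1 = ne.GeneValueTable({f"g{i}": float(v) for i, v in enumerate(vals)})
        t2 = ne.GeneValueTable({f"g{i}": float(v + 100.0) for i, v in enumerate(vals)})
        s = gs({f"g{i}" for i in range(0, 8)})
        r1 = ne.afc_test(t1, s, n_perm=2000, seed=5, exhaustive_limit=10)
        r2 = ne.afc_test(t2, s, n_perm=2000, seed=5, exhaustive_limit=10)
        assert r1.p_raw == pytest.approx(r2.p_raw)
        assert r2.statistic == pytest.approx(r1.statistic + 100.0)


class TestKS:
    def test_complete_separation_exact_p(self):
        t = ne.GeneValueTable({f"g{i}": float(i) for i in range(1, 7)})
        r = ne.ks_rank_test(t, gs({"g4", "g5", "g6"}))
        assert r.statistic == pytest.approx(1.0)
        assert r.p_raw == pytest.approx(2 * math.factorial(3) ** 2 / math.factorial(6))
        assert r.direction == "up"

    def test_single_extreme_gene_matches_placement_enumeration(self):
        # oracle: for each of the 10 possible ranks of the single in-set
        # gene, compute the two-sample D; exact p = fraction of placements
        # with D >= observed
        def d_of(rank, n=10):
            out = [r for r in range(1, n + 1) if r != rank]
            grid = sorted(range(1, n + 1))
            dmax = 0.0
            for x in grid:
                f_in = 1.0 if rank <= x else 0.0
                f_out = sum(r <= x for r in out) / len(out)
                dmax = max(dmax, abs(f_in - f_out))
            return dmax
        ds = [d_of(r) for r in range(1, 11)]
        t = ne.GeneValueTable({f"g{i}": float(i) for i in range(10)})
        r = ne.ks_rank_test(t, gs({"g9"}))
        assert r.statistic == pytest.approx(max(ds))
        expected_p = np.mean([d >= r.statistic - 1e-12 for d in ds])
        assert r.p_raw == pytest.approx(expected_p)

    def test_tied_identical_rank_multisets_give_p_one(self):
        t = ne.GeneValueTable(
            {"a": 1.0, "b": 1.0, "c": 2.0, "d": 2.0, "e": 3.0, "f": 3.0}
        )
        r = ne.ks_rank_test(t, gs({"a", "c", "e"}))
        assert r.p_raw == pytest.approx(1.0)

    def test_degenerate_split_skipped(self):
        t = ne.GeneValueTable({"a": 1.0, "b": 2.0})
        assert ne.ks_rank_test(t, gs({"a", "b"})) is None
        assert ne.ks_rank_test(t, gs({"zzz"})) is None

    def test_one_sample_mode_runs(self):
        t = ne.GeneValueTable({f"g{i}": float(i) for i in range(50)})
        r = ne.ks_rank_test(t, gs({f"g{i}" for i in range(40, 50)}), mode="one_sample")
        assert 0.0 <= r.p_raw <= 1.0 and r.direction == "up"


class TestBH:
    def test_equal_spaced_example(self):
        rs = [
            ne.EnrichmentResult(f"s{i}", "F", 1, 0.0, "up", p, "AFC")
            for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
        ]
        out = ne.bh_within_framework(rs)
        assert [r.q_bh for r in out] == pytest.approx([0.04] * 4)

    def test_stepup_minimum_example(self):
        rs = [
            ne.EnrichmentResult(f"s{i}", "F", 1, 0.0, "up", p, "AFC")
            for i, p in enumerate([0.01, 0.04, 0.03])
        ]
        out = ne.bh_within_framework(rs)
        assert [r.q_bh for r in out] == pytest.approx([0.03, 0.04, 0.04])

    def test_single_result_q_equals_p(self):
        out = ne.bh_within_framework(
            [ne.EnrichmentResult("s", "F", 1, 0.0, "up", 0.2, "AFC")]
        )
        assert out[0].q_bh == pytest.approx(0.2)

    def test_frameworks_corrected_separately(self):
        rs = [
            ne.EnrichmentResult("a", "F1", 1, 0.0, "up", 0.01, "AFC"),
            ne.EnrichmentResult("b", "F1", 1, 0.0, "up", 0.02, "AFC"),
            ne.EnrichmentResult("c", "F2", 1, 0.0, "up", 0.01, "AFC"),
        ]
        out = ne.bh_within_framework(rs)
        # c alone in F2: q = p; pooling with F1 would give 0.015
        assert out[2].q_bh == pytest.approx(0.01)
        assert out[0].q_bh == pytest.approx(0.02)

    @settings(max_examples=50, derandomize=True)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=100))
    def test_matches_brute_force_stepup_oracle(self, p):
        rs = [
            ne.EnrichmentResult(f"s{i}", "F", 1, 0.0, "up", pi, "AFC")
            for i, pi in enumerate(p)
        ]
        out = ne.bh_within_framework(rs)
        assert np.allclose([r.q_bh for r in out], bh_stepup_oracle(p))


class TestRunEnrichment:
    def test_routing_by_effective_size(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i:04d}" for i in range(2000)]
        t = ne.GeneValueTable({g: float(v) for g, v in zip(genes, rng.normal(size=2000))})
        coll = ne.GeneSetCollection("fw", [
            ne.GeneSet("small", "", frozenset(genes[:50])),
            ne.GeneSet("large", "", frozenset(genes[:1500])),
        ])
        cfg = ne.EnrichmentConfig(large_set_threshold=1000, n_perm=200, seed=9)
        out = ne.run_enrichment(t, [coll], cfg)
        methods = {r.set_id: r.method for r in out}
        assert methods == {"small": "AFC", "large": "KS"}

    def test_disjoint_table_gives_empty_results(self):
        t = ne.GeneValueTable({"x": 1.0, "y": 2.0})
        coll = ne.GeneSetCollection("fw", [ne.GeneSet("s", "", frozenset({"a", "b"}))])
        assert ne.run_enrichment(t, [coll]) == []

    def test_results_sorted_and_q_filled(self):
        rng = np.random.default_rng(14)
        genes = [f"g{i:03d}" for i in range(100)]
        t = ne.GeneValueTable({g: float(v) for g, v in zip(genes, rng.normal(size=100))})
        sets = [ne.GeneSet(f"s{i}", "", frozenset(rng.choice(genes, 10, replace=False)))
                for i in range(5)]
        out = ne.run_enrichment(t, [ne.GeneSetCollection("fw", sets)],
                                ne.EnrichmentConfig(n_perm=300, seed=2))
        assert all(r.q_bh is not None for r in out)
        keys = [(r.framework, r.q_bh, r.p_raw, r.set_id) for r in out]
        assert keys == sorted(keys)

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(16)
        vals = rng.normal(size=30)
        t1 = ne.GeneValueTable({f"g{i}": float(v) for i, v in enumerate(vals)})
        t2 = ne.GeneValueTable({f"XX{i}": float(v) for i, v in enumerate(vals)})
        s1 = gs({f"g{i}" for i in range(6)})
        s2 = gs({f"XX{i}" for i in range(6)})
        r1 = ne.afc_test(t1, s1, exhaustive_limit=10**6)
        r2 = ne.afc_test(t2, s2, exhaustive_limit=10**6)
        assert r1.p_raw == pytest.approx(r2.p_raw)


class TestGeneValueTable:
    def test_from_tsv_with_and_without_header(self, tmp_path):
        p1 = tmp_path / "h.tsv"
        p1.write_text("gene\tvalue\ng1\t1.5\ng2\t-0.5\n")
        p2 = tmp_path / "nh.tsv"
        p2.write_text("g1\t1.5\ng2\t-0.5\n")
        assert ne.GeneValueTable.from_tsv(p1).values == ne.GeneValueTable.from_tsv(p2).values

    def test_round_trip(self, tmp_path, small_value_table):
        p = tmp_path / "v.tsv"
        small_value_table.to_tsv(p)
        assert ne.GeneValueTable.from_tsv(p).values == small_value_table.values

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            ne.GeneValueTable({"a": float("nan"), "b": 1.0})
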