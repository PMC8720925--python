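"""GMT/disease ingestion, hypergeometric tail, BH adjustment, enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvnet.enrichment import (
    EnrichParams,
    GeneSetCollection,
    bh_adjust,
    enrich,
    hypergeom_upper,
    read_disease_tsv,
    read_gmt,
    results_table,
)


def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Oracle: exact rational summation of the hypergeometric mass."""
    return sum(
        Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
        for i in range(k, min(n, K) + 1)
    )


class TestReadGmt:
    def test_two_line_fixture(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tfirst\ta\tb\tc\nS2\tsecond\ta\tb\tc\td\te\n")
        coll = read_gmt(p)
        assert len(coll) == 2
        assert len(coll.sets["S1"][1]) == 3
        assert len(coll.sets["S2"][1]) == 5

    def test_repeated_gene_counts_once(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tx\tg1\tg1\tg2\n")
        assert len(read_gmt(p).sets["S1"][1]) == 2

    def test_duplicate_term_id_and_short_line_errors(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S1\tx\tg1\nS1\ty\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)
        q = tmp_path / "short.gmt"
        q.write_text("S1\tonly-description\n")
        with pytest.raises(ValueError, match="fewer than 3"):
            read_gmt(q)

    def test_disease_tsv_groups_rows(self, tmp_path):
        p = tmp_path / "dis.tsv"
        p.write_text(
            "disease_id\tdisease_name\tgene\n"
            "D1\tmood disorders\thcrt\nD1\tmood disorders\tHTR2A\n"
            "D2\tother\tKALRN\n"
        )
        coll = read_disease_tsv(p)
        assert coll.kind == "disease"
        assert coll.sets["D1"][1] == frozenset({"HCRT", "HTR2A"})


class TestHypergeom:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper(0, 5, 5, 20) == 1.0

    def test_full_overlap_closed_form(self):
        # P(all 5 draws in the 5-gene set) = 1/C(20,5)
        assert hypergeom_upper(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-9)

    def test_bounds_violations_rejected(self):
        for bad in [(3, 2, 5, 10), (1, 5, 11, 10), (-1, 2, 2, 10)]:
            with pytest.raises(ValueError):
                hypergeom_upper(*bad)

    def test_matches_exact_rational_summation_small_universe(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        expected = float(exact_upper_tail(k, K, n, N))
                        assert hypergeom_upper(k, K, n, N) == pytest.approx(
                            expected, rel=1e-10, abs=1e-300
                        )


class TestBhAdjust:
    def test_step_up_hand_evaluation(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        # 0.005*4/1, then min over the step-up of the rest
        assert bh_adjust([0.005, 0.1, 0.2, 0.9]) == pytest.approx(
            [0.02, 0.2, 0.8 / 3, 0.9]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == [0.3]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_bounds_and_statsmodels_agreement(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = bh_adjust(pvals)
        assert all(x >= p - 1e-15 for x, p in zip(adj, pvals))
        assert all(x <= 1.0 for x in adj)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert adj == pytest.approx(list(ref), rel=1e-12)


def make_collection():
    return GeneSetCollection(
        sets={
            "T1": ("target", frozenset({"A", "B", "C", "D"})),
            "T2": ("decoy1", frozenset({"E", "F", "G"})),
            "T3": ("decoy2", frozenset({"H", "I", "J", "K", "L"})),
        }
    )


class TestEnrich:
    def test_perfect_overlap_ranks_first_with_minimal_p(self):
        coll = make_collection()
        res = enrich({"A", "B", "C", "D"}, coll)
        assert res[0].term_id == "T1"
        assert res[0].k == 4
        # minimal achievable p for a size-4 query against a size-4 set
        assert res[0].p == pytest.approx(1 / comb(12, 4), rel=1e-9)

    def test_disjoint_query_empty_result(self):
        with pytest.warns(UserWarning):
            assert enrich({"ZZZ"}, make_collection()) == []

    def test_universe_override_changes_background(self):
        coll = make_collection()
        res_small = enrich({"A", "B"}, coll)
        res_big = enrich(
            {"A", "B"}, coll, universe=set("ABCDEFGHIJKL") | {f"X{i}" for i in range(20)}
        )
        t1_small = [r for r in res_small if r.term_id == "T1"][0]
        t1_big = [r for r in res_big if r.term_id == "T1"][0]
        assert t1_big.N == 32
        assert t1_big.p < t1_small.p  # same overlap, larger universe

    def test_adding_a_member_gene_never_raises_p(self):
        coll = make_collection()
        base = enrich({"A", "E"}, coll)
        more = enrich({"A", "B", "E"}, coll)
        p_base = [r.p for r in base if r.term_id == "T1"][0]
        p_more = [r.p for r in more if r.term_id == "T1"][0]
        assert p_more <= p_base

    def test_adjustment_invariant_under_term_permutation(self):
        coll = make_collection()
        perm = GeneSetCollection(sets=dict(reversed(list(coll.sets.items()))))
        res_a = enrich({"A", "B", "E"}, coll)
        res_b = enrich({"A", "B", "E"}, perm)
        assert {(r.term_id, r.p_adj) for r in res_a} == {
            (r.term_id, r.p_adj) for r in res_b
        }

    def test_null_rejection_rate_close_to_nominal(self):
        """P(p <= 0.05) under a uniform-query null stays near (below) 0.05."""
        rng = np.random.default_rng(123)
        universe = [f"G{i}" for i in range(600)]
        coll = GeneSetCollection(
            sets={"T": ("one set", frozenset(universe[:300]))}
        )
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            q = rng.choice(universe, size=90, replace=False)
            res = enrich(q, coll, universe=universe)
            p = res[0].p if res else 1.0
            hits += p <= 0.05
        assert 0.03 <= hits / n_rep <= 0.07

    def test_results_table_ratio_columns(self):
        res = enrich({"A", "B"}, make_collection())
        tab = results_table(res)
        row = tab[tab.term_id == "T1"].iloc[0]
        assert row.GeneRatio == "2/2"
        assert row.BgRatio == "4/12"

    def test_storey_q_never_exceeds_bh(self):
        coll = make_collection()
        res_bh = enrich({"A", "B", "E"}, coll)
        res_st = enrich({"A", "B", "E"}, coll, EnrichParams(q_method="storey"))
        for rb, rs in zip(res_bh, res_st):
            assert rs.q <= rb.q + 1e-12

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            enrich({"A"}, GeneSetCollection(sets={}))
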