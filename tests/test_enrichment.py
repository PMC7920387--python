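import math
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tspath.enrichment import (
    PathwayDB,
    enrich,
    hypergeom_pvalue,
    random_set_significance,
)


def exact_upper_tail(overlap, query, pathway, universe):
    """Combinatorial oracle: P(X >= overlap) via the hypergeometric pmf
    written out with binomial coefficients."""
    total = math.comb(universe, query)
    acc = 0
    for i in range(overlap, min(query, pathway) + 1):
        acc += math.comb(pathway, i) * math.comb(universe - pathway, query - i)
    return acc / total


class TestHypergeomPvalue:
    def test_full_containment_exact(self):
        # all 5 query genes inside a 5-gene pathway of a 10-gene universe:
        # C(5,5)/C(10,5) = 1/252
        assert hypergeom_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_is_one(self):
        assert hypergeom_pvalue(0, 5, 5, 10) == pytest.approx(1.0)

    def test_pathway_equals_universe(self):
        assert hypergeom_pvalue(4, 4, 10, 10) == pytest.approx(1.0)

    def test_precondition_violations(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_pvalue(2, 5, 11, 10)

    @pytest.mark.parametrize("universe", [8, 12])
    def test_matches_combinatorial_enumeration(self, universe):
        for pathway in range(1, universe + 1):
            for query in range(1, universe + 1):
                for overlap in range(0, min(pathway, query) + 1):
                    expected = exact_upper_tail(overlap, query, pathway,
                                                universe)
                    got = hypergeom_pvalue(overlap, query, pathway, universe)
                    assert got == pytest.approx(expected, rel=1e-10)

    @given(st.integers(20, 200), st.integers(1, 19), st.integers(1, 19))
    @settings(max_examples=40, deadline=None)
    def test_non_increasing_in_overlap(self, universe, pathway, query):
        prev = 1.1
        for overlap in range(0, min(pathway, query) + 1):
            p = hypergeom_pvalue(overlap, query, pathway, universe)
            assert p <= prev + 1e-12
            prev = p

    def test_ease_variant_is_more_conservative(self):
        p_plain = hypergeom_pvalue(4, 5, 5, 20)
        p_ease = hypergeom_pvalue(4, 5, 5, 20, ease=True)
        assert p_ease > p_plain
        assert p_ease == pytest.approx(hypergeom_pvalue(3, 5, 5, 20))


class TestEnrich:
    @pytest.fixture
    def db(self):
        # P1 fully covered by the query; P2 disjoint; P3 too small a hit
        pathways = {
            "P1": [f"a{i}" for i in range(6)],
            "P2": [f"b{i}" for i in range(6)],
            "P3": [f"c{i}" for i in range(6)] + ["a0"],
        }
        background = [f"x{i}" for i in range(80)]
        return PathwayDB.build(pathways, background=background)

    def test_planted_pathway_retained(self, db):
        query = {f"a{i}" for i in range(6)}
        results = enrich(query, db, p_max=0.001, min_count=5)
        assert [r.pathway_id for r in results] == ["P1"]
        assert results[0].overlap_count == 6

    def test_min_count_filters_regardless_of_p(self, db):
        query = {f"a{i}" for i in range(4)}  # overlap 4 with P1, p tiny
        assert enrich(query, db, p_max=1.0, min_count=5) == []
        kept = enrich(query, db, p_max=1.0, min_count=4)
        assert any(r.pathway_id == "P1" for r in kept)

    def test_disjoint_query_returns_empty(self, db):
        assert enrich({"zzz"}, db, p_max=1.0, min_count=0) == []

    def test_empty_db(self):
        db = PathwayDB(pathways={}, universe=frozenset({"a"}))
        assert enrich({"a"}, db) == []

    def test_sorted_by_pvalue_then_id(self, db):
        query = ({f"a{i}" for i in range(6)} | {f"b{i}" for i in range(6)})
        results = enrich(query, db, p_max=1.0, min_count=1)
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_bh_column_monotone_with_p(self, db):
        query = {f"a{i}" for i in range(6)} | {"c0", "c1"}
        results = enrich(query, db, p_max=1.0, min_count=1)
        for r in results:
            assert r.bh_q >= r.p_value - 1e-12


class TestRandomSetSignificance:
    @pytest.fixture
    def setup(self):
        pathways = {"P1": [f"m{i}" for i in range(10)]}
        background = [f"n{i}" for i in range(60)]
        db = PathwayDB.build(pathways, background=background)
        network_genes = set(db.universe)
        seeds = {"m0", "m1"}
        observed = {f"m{i}" for i in range(10)}  # the whole planted pathway
        return db, network_genes, seeds, observed

    def test_observed_beats_every_draw(self, setup):
        db, network_genes, seeds, observed = setup
        null = random_set_significance(network_genes, seeds, observed,
                                       n_draws=50, db=db, p_max=0.05,
                                       min_count=3, rng_seed=1)
        assert null.observed == 10
        assert null.empirical_p == pytest.approx(1 / 51)

    def test_add_one_rule(self, setup):
        db, network_genes, seeds, observed = setup
        null = random_set_significance(network_genes, seeds, observed,
                                       n_draws=20, db=db, p_max=0.05,
                                       min_count=3, rng_seed=2)
        n_ge = sum(1 for d in null.draws if d >= null.observed)
        assert null.empirical_p == pytest.approx((1 + n_ge) / 21)

    def test_deterministic_under_seed(self, setup):
        db, network_genes, seeds, observed = setup
        kw = dict(n_draws=15, db=db, p_max=0.05, min_count=3, rng_seed=9)
        a = random_set_significance(network_genes, seeds, observed, **kw)
        b = random_set_significance(network_genes, seeds, observed, **kw)
        assert a == b

    def test_draw_size_exhausts_pool(self, setup):
        db, network_genes, seeds, observed = setup
        pool = len(frozenset(network_genes) - seeds)
        null = random_set_significance(network_genes, seeds, observed,
                                       n_draws=5, db=db, rng_seed=0,
                                       draw_size=pool)
        assert len(set(null.draws)) == 1  # every draw is the full pool
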