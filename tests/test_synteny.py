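"""Neighborhoods, SyS and SyC against exhaustive brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from genfamclust import (
    GeneOrderMap,
    SyntenyParams,
    nc_hits,
    neighborhood,
    syc_score,
    synteny_all,
    sys_score,
)
from genfamclust.nc import NCGraph


def make_nc_graph(edges: dict[tuple[str, str], float]) -> NCGraph:
    graph = NCGraph()
    for (g1, g2), v in edges.items():
        graph.add(g1, g2, v)
    return graph


def brute_sys(nc: NCGraph, order: GeneOrderMap, g1: str, g2: str, k: int) -> float:
    """Oracle: exhaustive max over the neighbor product set."""
    best = 0.0
    for a in order.neighborhood(g1, k):
        for b in order.neighborhood(g2, k):
            best = max(best, nc.nc(a, b, 0.0))
    return best


@pytest.fixture
def two_species_order() -> GeneOrderMap:
    rows = []
    for sp in ("A", "B"):
        for i in range(10):
            rows.append((f"{sp}{i}", sp, "c1", float(i)))
    return GeneOrderMap(rows)


def random_instance(seed: int, density: float = 0.3):
    """Seeded random NC graph over two 10-gene contigs."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp in ("A", "B"):
        for i in range(10):
            rows.append((f"{sp}{i}", sp, "c1", float(i)))
    order = GeneOrderMap(rows)
    genes = [g for g, *_ in rows]
    edges = {}
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            if rng.random() < density:
                edges[(g1, g2)] = float(rng.uniform(-0.2, 1.0))
    return order, make_nc_graph(edges)


class TestNeighborhood:
    def test_truncated_at_contig_start(self):
        order = GeneOrderMap([(f"g{i}", "S", "c", float(i)) for i in range(3)])
        assert neighborhood(order, "g0", 5) == ["g1", "g2"]

    def test_full_window_in_middle(self):
        order = GeneOrderMap([(f"g{i:02d}", "S", "c", float(i)) for i in range(11)])
        assert len(neighborhood(order, "g05", 5)) == 10

    def test_zero_radius_empty(self, two_species_order):
        assert neighborhood(two_species_order, "A5", 0) == []

    def test_unknown_gene_is_error(self, two_species_order):
        with pytest.raises(KeyError):
            neighborhood(two_species_order, "nope", 5)

    def test_excludes_the_gene_itself(self, two_species_order):
        assert "A5" not in neighborhood(two_species_order, "A5", 5)


class TestSysScore:
    def test_single_nc_edge_between_neighborhoods(self, two_species_order):
        nc = make_nc_graph({("A4", "B6"): 0.7})
        assert sys_score(nc, two_species_order, "A5", "B5") == 0.7

    def test_empty_neighborhood_gives_zero(self):
        order = GeneOrderMap([("solo", "S", "c0", 0.0), ("x", "T", "c1", 0.0)])
        nc = make_nc_graph({("solo", "x"): 0.9})
        assert sys_score(nc, order, "solo", "x") == 0.0

    def test_matches_bruteforce_max(self, two_species_order):
        nc = make_nc_graph(
            {("A4", "B4"): 0.2, ("A6", "B3"): 0.55, ("A3", "B6"): 0.41}
        )
        params = SyntenyParams(k=3)
        assert sys_score(nc, two_species_order, "A5", "B5", params) == 0.55
        assert sys_score(nc, two_species_order, "A5", "B5", params) == brute_sys(
            nc, two_species_order, "A5", "B5", 3
        )

    def test_symmetry_and_oracle_on_random_instances(self):
        for seed in range(4):
            order, nc = random_instance(seed)
            params = SyntenyParams(k=4)
            for g1, g2 in [("A2", "B7"), ("A0", "B9"), ("A5", "B5")]:
                v = sys_score(nc, order, g1, g2, params)
                assert v == sys_score(nc, order, g2, g1, params)
                assert v == brute_sys(nc, order, g1, g2, 4)

    def test_never_exceeds_global_max_nc(self):
        order, nc = random_instance(9)
        top = max(v for _, _, v in nc.edges())
        assert sys_score(nc, order, "A5", "B5", SyntenyParams(k=5)) <= max(top, 0.0)

    def test_shrinking_k_never_increases_sys(self):
        order, nc = random_instance(13)
        values = [
            sys_score(nc, order, "A5", "B4", SyntenyParams(k=k)) for k in (5, 3, 1, 0)
        ]
        assert values == sorted(values, reverse=True)


class TestNcHits:
    def test_threshold_above_max_gives_empty(self):
        nc = make_nc_graph({("a", "b"): 0.4, ("a", "c"): 0.6})
        assert nc_hits(nc, "a", 0.7) == set()

    def test_minus_one_gives_all_partners(self):
        nc = make_nc_graph({("a", "b"): 0.4, ("a", "c"): -0.1})
        assert nc_hits(nc, "a", -1.0) == {"b", "c"}

    def test_filter_is_inclusive_at_beta(self):
        nc = make_nc_graph({("a", "b"): 0.3, ("a", "c"): 0.29})
        assert nc_hits(nc, "a", 0.3) == {"b"}


class TestSycScore:
    def test_empty_shared_hits_gives_zero(self, two_species_order):
        nc = make_nc_graph({("A5", "B5"): 0.5})
        value, h_size = syc_score(nc, two_species_order, "A5", "B5", SyntenyParams())
        assert value == 0.0 and h_size < 2

    def test_identical_nondegenerate_sys_vectors_give_one(self, two_species_order):
        # A5 and B5 share NC hits {A1, B1, A8, B8}; symmetric neighborhoods
        # produce identical SyS vectors with real variation
        edges = {}
        for i in ("A1", "B1", "A8", "B8"):
            edges[("A5", i)] = 0.8
            edges[("B5", i)] = 0.8
        # synteny context: neighbor-level NC edges of different strengths
        edges[("A4", "A2")] = 0.9   # supports SyS(A5, A1) and SyS(B5, ..)
        edges[("B4", "A2")] = 0.9
        edges[("A4", "B2")] = 0.6
        edges[("B4", "B2")] = 0.6
        edges[("A6", "A7")] = 0.3
        edges[("B6", "A7")] = 0.3
        edges[("B6", "B7")] = 0.3
        nc = make_nc_graph(edges)
        params = SyntenyParams(k=2, beta=0.3)
        xs = [sys_score(nc, two_species_order, "A5", i, params) for i in ("A1", "A8", "B1", "B8")]
        ys = [sys_score(nc, two_species_order, "B5", i, params) for i in ("A1", "A8", "B1", "B8")]
        assert xs == ys and len(set(xs)) > 1
        value, h_size = syc_score(nc, two_species_order, "A5", "B5", params)
        assert h_size == 4
        assert value == pytest.approx(1.0)

    def test_matches_bruteforce_pearson_over_materialized_sys(self):
        """SyC equals numpy Pearson of explicitly computed SyS vectors."""
        for seed in (3, 21):
            order, nc = random_instance(seed, density=0.4)
            params = SyntenyParams(k=3, beta=0.2)
            g1, g2 = "A5", "B4"
            shared = sorted(nc_hits(nc, g1, params.beta) & nc_hits(nc, g2, params.beta))
            if len(shared) < 2:
                continue
            xs = np.array([brute_sys(nc, order, g1, i, 3) for i in shared])
            ys = np.array([brute_sys(nc, order, g2, i, 3) for i in shared])
            expected = (
                0.0
                if xs.std() == 0 or ys.std() == 0
                else float(np.corrcoef(xs, ys)[0, 1])
            )
            value, h_size = syc_score(nc, order, g1, g2, params)
            assert h_size == len(shared)
            assert value == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments(self):
        order, nc = random_instance(5, density=0.5)
        params = SyntenyParams(k=3, beta=0.1)
        v1, _ = syc_score(nc, order, "A3", "B6", params)
        v2, _ = syc_score(nc, order, "B6", "A3", params)
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestSyntenyAll:
    def test_beta_one_gives_empty_graph(self):
        order, nc = random_instance(2)
        graph = synteny_all(nc, order, SyntenyParams(beta=1.0))
        assert len(graph) == 0

    def test_candidate_selection_is_strict_above_beta(self, two_species_order):
        nc = make_nc_graph({("A1", "B1"): 0.3, ("A2", "B2"): 0.31})
        graph = synteny_all(nc, two_species_order, SyntenyParams(beta=0.3))
        assert graph.pairs() == [("A2", "B2")]

    def test_per_pair_values_match_oracle_recomputation(self):
        order, nc = random_instance(17, density=0.35)
        params = SyntenyParams(k=3, beta=0.2)
        graph = synteny_all(nc, order, params)
        assert len(graph) > 0
        for (g1, g2), rec in graph.items():
            assert rec.sys == brute_sys(nc, order, g1, g2, 3)
            value, h_size = syc_score(nc, order, g1, g2, params)
            assert rec.syc == pytest.approx(value, abs=1e-12)
            assert rec.h_size == h_size
            assert rec.nc == nc.nc(g1, g2)

    def test_memoized_sys_agrees_with_direct(self):
        order, nc = random_instance(23, density=0.4)
        params = SyntenyParams(k=4, beta=0.1)
        memo: dict = {}
        for g1, g2 in [("A1", "B2"), ("A1", "B2"), ("B2", "A1")]:
            assert sys_score(nc, order, g1, g2, params, memo) == sys_score(
                nc, order, g1, g2, params
            )
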