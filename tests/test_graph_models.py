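"""Generator correctness: exact counts, distributional checks, invariants."""

import numpy as np
import pytest
from scipy import stats

from netspect import graph_models as gm
from netspect.divergence import js_divergence
from netspect.spectral import adjacency_spectrum, shared_grid, spectral_density

ALL_GENERATORS = [
    ("erdos_renyi_gnp", lambda s: gm.erdos_renyi_gnp(20, 0.3, s)),
    ("erdos_renyi_gnm", lambda s: gm.erdos_renyi_gnm(20, 40, s)),
    ("geometric", lambda s: gm.geometric_graph(20, 0.3, s)),
    ("k_regular", lambda s: gm.k_regular(20, 4, s)),
    ("watts_strogatz", lambda s: gm.watts_strogatz(20, 4, 0.3, s)),
    ("preferential_attachment", lambda s: gm.preferential_attachment(20, 3, 1.5, s)),
]


class TestGraphType:
    def test_canonicalizes_and_validates(self):
        g = gm.Graph.from_edges(3, [(2, 1), (0, 1)])
        assert g.edges == frozenset({(1, 2), (0, 1)})
        with pytest.raises(ValueError):
            gm.Graph.from_edges(3, [(0, 0)])
        with pytest.raises(ValueError):
            gm.Graph.from_edges(3, [(0, 3)])
        with pytest.raises(ValueError):
            gm.Graph(0)

    def test_adjacency_and_degrees(self):
        g = gm.Graph.from_edges(3, [(0, 1), (1, 2)])
        a = g.adjacency()
        assert np.array_equal(a, a.T)
        assert a.sum() == 4
        assert g.degrees().tolist() == [1, 2, 1]


class TestErdosRenyi:
    def test_gnp_extremes(self):
        assert gm.erdos_renyi_gnp(50, 0.0, 0).n_edges == 0
        assert gm.erdos_renyi_gnp(50, 1.0, 0).n_edges == 1225

    def test_gnp_domain_errors(self):
        with pytest.raises(ValueError):
            gm.erdos_renyi_gnp(10, 1.1, 0)
        with pytest.raises(ValueError):
            gm.erdos_renyi_gnp(10, -0.1, 0)
        with pytest.raises(ValueError):
            gm.erdos_renyi_gnp(0, 0.5, 0)

    def test_gnp_mean_edge_count_matches_binomial(self):
        # E|E| = C(100,2) * 0.2 = 990, sd per draw = sqrt(npq)
        counts = [gm.erdos_renyi_gnp(100, 0.2, s).n_edges for s in range(200)]
        se = np.sqrt(4950 * 0.2 * 0.8 / 200)
        assert abs(np.mean(counts) - 990.0) < 3 * se

    def test_gnp_edge_count_distribution_binomial_gof(self):
        # chi-square GOF of edge counts against Binomial(C(12,2), 0.3)
        n, p, draws = 12, 0.3, 2000
        total = n * (n - 1) // 2
        counts = np.array(
            [gm.erdos_renyi_gnp(n, p, s).n_edges for s in range(draws)]
        )
        dist = stats.binom(total, p)
        # bin the support so every expected count is >= 5
        edges = [0]
        acc = 0.0
        for k in range(total + 1):
            acc += dist.pmf(k) * draws
            if acc >= 5 and k + 1 <= total:
                edges.append(k + 1)
                acc = 0.0
        edges[-1] = total + 1
        observed = np.histogram(counts, bins=edges)[0]
        expected = np.array(
            [dist.cdf(edges[i + 1] - 1) - dist.cdf(edges[i] - 1)
             for i in range(len(edges) - 1)]
        ) * draws
        expected *= observed.sum() / expected.sum()
        pvalue = stats.chisquare(observed, expected).pvalue
        assert pvalue > 0.01

    @pytest.mark.parametrize(
        "n,m,expected",
        [(100, 1000, 1000), (10, 0, 0), (10, 45, 45)],
    )
    def test_gnm_exact_edge_count(self, n, m, expected):
        assert gm.erdos_renyi_gnm(n, m, 0).n_edges == expected

    def test_gnm_too_many_edges(self):
        with pytest.raises(ValueError):
            gm.erdos_renyi_gnm(10, 46, 0)


class TestGeometric:
    def test_radius_extremes(self):
        assert gm.geometric_graph(30, 0.0, 0).n_edges == 0
        full = gm.geometric_graph(30, np.sqrt(2) + 1e-9, 0)
        assert full.n_edges == 30 * 29 // 2

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            gm.geometric_graph(10, -0.1, 0)

    def test_edge_density_matches_geometric_probability(self):
        # independent Monte-Carlo estimate of P(|X - Y| < r) for uniform
        # points in the unit square (the generator is not used here)
        r = 0.25
        mc_rng = np.random.default_rng(99)
        x = mc_rng.random((200_000, 2))
        y = mc_rng.random((200_000, 2))
        p_edge = np.mean(np.linalg.norm(x - y, axis=1) < r)
        densities = [
            gm.geometric_graph(100, r, s).n_edges / 4950 for s in range(200)
        ]
        se = np.sqrt(np.var(densities) / 200 + p_edge * (1 - p_edge) / 200_000)
        assert abs(np.mean(densities) - p_edge) < 3 * se + 1e-4


class TestKRegular:
    def test_all_degrees_equal(self):
        g = gm.k_regular(10, 2, 0)
        assert set(g.degrees().tolist()) == {2}

    def test_odd_degree_sum_infeasible(self):
        with pytest.raises(gm.PairingFailedError):
            gm.k_regular(9, 3, 0)

    def test_degree_too_large(self):
        with pytest.raises(ValueError):
            gm.k_regular(5, 5, 0)

    def test_leading_eigenvalue_equals_degree(self):
        # lambda_1 of a k-regular graph equals k
        spec = adjacency_spectrum(gm.k_regular(100, 6, 1))
        assert abs(spec.values[0] - 6.0) < 1e-8


class TestWattsStrogatz:
    def test_ring_lattice(self):
        g = gm.watts_strogatz(100, 20, 0.0, 0)
        assert g.n_edges == 1000
        assert set(g.degrees().tolist()) == {20}

    def test_edge_count_conserved_under_rewiring(self):
        for p in (0.1, 0.5, 1.0):
            assert gm.watts_strogatz(100, 20, p, 3).n_edges == 1000

    def test_odd_k_rejected(self):
        with pytest.raises(ValueError):
            gm.watts_strogatz(10, 3, 0.1, 0)

    def test_full_rewiring_approaches_erdos_renyi_spectrum(self):
        # at p=1 the spectral density nears the ER semicircle; JS to an
        # ER graph with the same edge count drops below any p <= 0.3
        n, k = 500, 16
        m = n * k // 2
        er = adjacency_spectrum(gm.erdos_renyi_gnm(n, m, 7))
        js = {}
        for p in (0.0, 0.1, 0.2, 0.3, 1.0):
            ws = adjacency_spectrum(gm.watts_strogatz(n, k, p, 11))
            grid = shared_grid([ws, er])
            js[p] = js_divergence(
                spectral_density(ws, grid), spectral_density(er, grid)
            )
        assert js[1.0] < min(js[p] for p in (0.0, 0.1, 0.2, 0.3))


class TestPreferentialAttachment:
    def test_edge_count_formula(self):
        # clique C(10,2) plus 90 new vertices with 10 edges each
        assert gm.preferential_attachment(100, 10, 1.0, 0).n_edges == 945

    def test_clique_only(self):
        g = gm.preferential_attachment(5, 5, 2.0, 0)
        assert g.n_edges == 10

    def test_m_too_large(self):
        with pytest.raises(ValueError):
            gm.preferential_attachment(4, 5, 1.0, 0)

    def test_hub_formation_grows_with_exponent(self):
        def mean_max_degree(ps):
            return np.mean(
                [gm.preferential_attachment(200, 10, ps, s).degrees().max()
                 for s in range(100)]
            )

        assert mean_max_degree(3.0) > mean_max_degree(1.0)


class TestMarkovRewire:
    def test_zero_swaps_is_identity(self):
        g = gm.erdos_renyi_gnm(30, 100, 0)
        assert gm.markov_rewire(g, 0, 1).edges == g.edges

    def test_degree_sequence_conserved(self):
        g = gm.watts_strogatz(100, 20, 0.0, 0)
        rewired = gm.markov_rewire(g, 500, 1)
        assert rewired.n_vertices == g.n_vertices
        assert rewired.n_edges == g.n_edges
        assert sorted(rewired.degrees()) == sorted(g.degrees())
        assert rewired.edges != g.edges

    def test_complete_graph_admits_no_swap(self):
        k5 = gm.Graph.from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        with pytest.raises(gm.RewireInfeasibleError) as err:
            gm.markov_rewire(k5, 1, 0)
        assert err.value.swaps_completed == 0


class TestSharedInvariants:
    @pytest.mark.parametrize("name,make", ALL_GENERATORS)
    def test_many_seeded_draws_are_valid_simple_graphs(self, name, make):
        # Graph.__post_init__ enforces simplicity; construction succeeding
        # for hundreds of seeds is the invariant check
        for s in range(300):
            g = make(s)
            assert g.n_vertices == 20
            assert all(i < j for i, j in g.edges)

    @pytest.mark.parametrize("name,make", ALL_GENERATORS)
    def test_seeded_determinism(self, name, make):
        assert make(12345).edges == make(12345).edges
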