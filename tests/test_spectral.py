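"""Spectrum and density estimation: analytic cases, oracles, invariants."""

import itertools

import numpy as np
import pytest

from netspect import graph_models as gm
from netspect.divergence import js_divergence
from netspect.spectral import (
    SpectralDensity,
    Spectrum,
    adjacency_spectrum,
    kernel_bandwidth,
    mean_density,
    shared_grid,
    spectral_density,
    sturges_bins,
)


def exact_eigenvalues(a: np.ndarray) -> np.ndarray:
    """Independent eigenvalue oracle: exact symbolic solution of the
    characteristic polynomial over the integers (sympy), with
    multiplicities, evaluated to high precision."""
    import sympy

    vals = []
    for root, mult in sympy.Matrix(a.astype(int)).eigenvals().items():
        vals.extend([complex(sympy.N(root, 30)).real] * mult)
    return np.sort(np.asarray(vals))[::-1]


class TestAdjacencySpectrum:
    def test_triangle(self):
        g = gm.Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert np.allclose(adjacency_spectrum(g).values, [2, -1, -1])

    def test_empty_graph(self):
        g = gm.Graph.from_edges(5, [])
        assert np.allclose(adjacency_spectrum(g).values, np.zeros(5))

    def test_trace_identities(self):
        g = gm.erdos_renyi_gnp(60, 0.3, 5)
        v = adjacency_spectrum(g).values
        assert abs(v.sum()) < 1e-8                      # hollow matrix
        assert abs((v**2).sum() - 2 * g.n_edges) < 1e-8  # trace(A^2) = 2|E|

    def test_matches_exact_symbolic_oracle_on_small_graphs(self):
        # all graphs on 4 vertices, plus sampled 6-vertex graphs
        pairs4 = list(itertools.combinations(range(4), 2))
        for bits in range(64):
            edges = [e for i, e in enumerate(pairs4) if bits >> i & 1]
            g = gm.Graph.from_edges(4, edges)
            assert np.allclose(
                adjacency_spectrum(g).values,
                exact_eigenvalues(g.adjacency()),
                atol=1e-8,
            )
        for s in range(30):
            g = gm.erdos_renyi_gnp(6, 0.5, s)
            assert np.allclose(
                adjacency_spectrum(g).values,
                exact_eigenvalues(g.adjacency()),
                atol=1e-8,
            )

    def test_density_invariant_under_vertex_relabeling(self):
        g = gm.erdos_renyi_gnp(30, 0.2, 9)
        perm = np.random.default_rng(1).permutation(30)
        relabeled = gm.Graph.from_edges(
            30, [(perm[i], perm[j]) for i, j in g.edges]
        )
        s1, s2 = adjacency_spectrum(g), adjacency_spectrum(relabeled)
        grid = shared_grid([s1, s2])
        d1 = spectral_density(s1, grid)
        d2 = spectral_density(s2, grid)
        # eigenvalues are permutation invariant; allow eigensolver ulps
        assert np.allclose(d1.density, d2.density, rtol=0, atol=1e-12)


class TestSturgesAndBandwidth:
    @pytest.mark.parametrize("n,expected", [(1, 1), (30, 6), (100, 8)])
    def test_sturges(self, n, expected):
        assert sturges_bins(n) == expected

    def test_sturges_domain(self):
        with pytest.raises(ValueError):
            sturges_bins(0)

    def test_bandwidth_formula(self):
        assert kernel_bandwidth(Spectrum([2, -1, -1])) == pytest.approx(1.0)
        # spread 16 over 100 eigenvalues -> 16 / 8 bins
        values = np.linspace(8, -8, 100)
        assert kernel_bandwidth(Spectrum(values)) == pytest.approx(2.0)

    def test_degenerate_spread_falls_back(self):
        bw = kernel_bandwidth(Spectrum(np.zeros(5)))
        assert bw == pytest.approx(1e-3)
        bw = kernel_bandwidth(Spectrum(np.full(4, 5.0)))
        assert bw == pytest.approx(5e-3)


class TestSpectralDensity:
    def test_unit_area(self):
        for seed in range(5):
            g = gm.erdos_renyi_gnp(40, 0.2, seed)
            s = adjacency_spectrum(g)
            rho = spectral_density(s, shared_grid([s]))
            assert abs(rho.area - 1.0) < 1e-6

    def test_symmetric_spectrum_gives_symmetric_density(self):
        s = Spectrum([1.0, -1.0])
        h = kernel_bandwidth(s)
        half = 1.0 + 3 * h
        grid = np.linspace(-half, half, 401)  # symmetric about 0
        rho = spectral_density(s, grid)
        assert np.allclose(rho.density, rho.density[::-1], atol=1e-10)

    def test_mode_at_point_mass(self):
        s = Spectrum([2.5, 2.5, 2.5])
        grid = np.linspace(0, 5, 501)
        rho = spectral_density(s, grid)
        assert abs(grid[np.argmax(rho.density)] - 2.5) <= grid[1] - grid[0]

    def test_grid_must_cover_padded_support(self):
        s = Spectrum([2, -1, -1])
        with pytest.raises(ValueError):
            spectral_density(s, np.linspace(-2, 3, 100))

    def test_density_type_validation(self):
        grid = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            SpectralDensity(grid, np.full(10, 2.0), 1.0)  # area != 1
        with pytest.raises(ValueError):
            SpectralDensity(grid[::-1], np.full(10, 1.0), 1.0)


class TestSharedGrid:
    def test_padding_rule(self):
        grid = shared_grid([Spectrum([2, -1, -1])], 11)
        assert grid[0] == pytest.approx(-4.0)
        assert grid[-1] == pytest.approx(5.0)

    def test_identical_spectra_share_grid(self):
        s = Spectrum([2, -1, -1])
        assert np.array_equal(shared_grid([s, s]), shared_grid([s]))

    def test_resolution_and_uniformity(self):
        grid = shared_grid([Spectrum([1, 0, -1])], 512)
        assert grid.size == 512
        assert np.allclose(np.diff(grid), grid[1] - grid[0])

    def test_empty_collection(self):
        with pytest.raises(ValueError):
            shared_grid([])


class TestMeanDensity:
    def test_identity_cases(self):
        s = Spectrum([2, -1, -1])
        rho = spectral_density(s, shared_grid([s]))
        assert np.allclose(mean_density([rho]).density, rho.density)
        assert np.allclose(mean_density([rho] * 4).density, rho.density)

    def test_mean_keeps_unit_area(self):
        s1 = Spectrum([2, -1, -1])
        s2 = Spectrum([1.5, 0.0, -1.5])
        grid = shared_grid([s1, s2])
        m = mean_density([spectral_density(s1, grid), spectral_density(s2, grid)])
        assert abs(m.area - 1.0) < 1e-6

    def test_grid_mismatch_rejected(self):
        s = Spectrum([2, -1, -1])
        r1 = spectral_density(s, shared_grid([s], 100))
        r2 = spectral_density(s, shared_grid([s], 101))
        with pytest.raises(ValueError):
            mean_density([r1, r2])


class TestSizeConvergence:
    def test_rescaled_er_densities_converge_with_size(self):
        # with eigenvalues divided by |V|, independent ER(n, 0.2) pairs
        # get closer in JS as n grows
        medians = []
        for n in (30, 60, 120):
            js = []
            for s in range(50):
                rng = np.random.default_rng(1000 + s)
                a = adjacency_spectrum(gm.erdos_renyi_gnp(n, 0.2, rng))
                b = adjacency_spectrum(gm.erdos_renyi_gnp(n, 0.2, rng))
                sa, sb = Spectrum(a.values / n), Spectrum(b.values / n)
                grid = shared_grid([sa, sb])
                js.append(
                    js_divergence(
                        spectral_density(sa, grid), spectral_density(sb, grid)
                    )
                )
            medians.append(np.median(js))
        assert medians[0] > medians[1] > medians[2]
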