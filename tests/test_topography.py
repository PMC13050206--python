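"""Peak detection, ruggedness, closed-form predictions and Monte Carlo."""

import networkx as nx
import numpy as np
import pytest

from nclandscape import (
    DistributionSpec,
    NCGraph,
    PFMap,
    aggregate_peak_height_cdf,
    attach_fitness,
    draw_pf_map,
    expected_peak_count,
    expected_ruggedness,
    find_peaks,
    peak_height_cdf,
    peak_height_moments,
    peak_probability,
    ruggedness_of_realization,
    simulate_topography,
)


def _graph(nodes, edges, total=None):
    g = nx.Graph()
    for i, (phenotype, size) in enumerate(nodes):
        g.add_node(i, phenotype=phenotype, size=size)
    g.add_edges_from(edges)
    total = total if total is not None else sum(s for _, s in nodes)
    return NCGraph(graph=g, total_genotypes=total)


def _realize(graph, fitness_by_phenotype):
    pf = PFMap(fitness_of=fitness_by_phenotype, distribution=None)
    return attach_fitness(graph, pf)


class TestFindPeaks:
    def test_single_node_is_peak(self):
        g = _graph([("A", 3)], [])
        peaks = find_peaks(_realize(g, {"A": 0.4}))
        assert [p.nc_id for p in peaks] == [0]

    def test_two_adjacent_nodes_fitter_wins(self):
        g = _graph([("A", 1), ("B", 1)], [(0, 1)])
        peaks = find_peaks(_realize(g, {"A": 0.2, "B": 0.7}))
        assert [p.phenotype for p in peaks] == ["B"]

    def test_at_least_one_peak(self, fib3_graph, uniform_dist):
        for seed in range(10):
            pf = draw_pf_map(fib3_graph.phenotypes + ["DELETERIOUS"], uniform_dist, seed)
            assert len(find_peaks(attach_fitness(fib3_graph, pf))) >= 1

    def test_tie_is_an_error(self):
        g = _graph([("A", 1), ("B", 1)], [(0, 1)])
        with pytest.raises(ValueError, match="tie"):
            find_peaks(_realize(g, {"A": 0.5, "B": 0.5}))


class TestRuggedness:
    def test_single_nc_covering_everything(self):
        g = _graph([("A", 8)], [])
        assert ruggedness_of_realization(_realize(g, {"A": 0.3})) == 1.0

    def test_fibonacci_arithmetic(self, fib3_graph):
        # make only the size-9 empty-prefix NC a peak: give it top fitness
        # the empty-prefix NC is adjacent to all six others, so giving it the
        # top fitness makes it the unique peak
        fitness = {
            p: 0.1 + 0.05 * i
            for i, p in enumerate(sorted(fib3_graph.phenotypes, key=lambda q: (len(q), q)))
        }
        fitness[""] = 0.99
        real = _realize(fib3_graph, fitness)
        assert {p.phenotype for p in find_peaks(real)} == {""}
        assert ruggedness_of_realization(real) == pytest.approx(9 / 27)

    def test_deleterious_presence_keeps_ruggedness_below_one(self, fib3_graph, uniform_dist):
        pf = draw_pf_map(fib3_graph.phenotypes + ["DELETERIOUS"], uniform_dist, 3)
        assert ruggedness_of_realization(attach_fitness(fib3_graph, pf)) < 1.0


class TestClosedForms:
    @pytest.mark.parametrize("eps, expected", [(0, 1.0), (2, 1 / 3), (6, 1 / 7)])
    def test_peak_probability(self, eps, expected):
        assert peak_probability(eps) == pytest.approx(expected)

    def test_peak_probability_recovers_hoc(self):
        # with eps = (K-1)L the House-of-Cards value 1/((K-1)L + 1) is recovered
        K, L = 3, 12
        assert peak_probability((K - 1) * L) == pytest.approx(1 / ((K - 1) * L + 1))

    def test_negative_evolvability_rejected(self):
        with pytest.raises(ValueError):
            peak_probability(-1)

    def test_expected_peak_count_fibonacci(self, fib3_graph):
        assert expected_peak_count(fib3_graph) == pytest.approx(47 / 35)

    def test_expected_peak_count_mutually_adjacent(self):
        n = 5
        g = _graph([(f"p{i}", 1) for i in range(n)], [(i, j) for i in range(n) for j in range(i)])
        assert expected_peak_count(g) == pytest.approx(1.0)

    def test_expected_peak_count_isolated(self):
        assert expected_peak_count(_graph([("A", 1)], [])) == 1.0

    def test_expected_ruggedness_fibonacci(self, fib3_graph):
        assert expected_ruggedness(fib3_graph) == pytest.approx(23 / 189)

    def test_expected_ruggedness_degenerate(self):
        assert expected_ruggedness(_graph([("A", 16)], [])) == 1.0
        # all-singleton isolated graph, no deleterious genotypes
        g = _graph([(f"p{i}", 1) for i in range(6)], [])
        assert expected_ruggedness(g) == 1.0


class TestPeakHeightCDF:
    def test_uniform_examples(self, uniform_dist):
        assert peak_height_cdf(1, uniform_dist, 0.5) == pytest.approx(0.25)
        assert peak_height_cdf(0, uniform_dist, 0.3) == pytest.approx(0.3)
        assert peak_height_cdf(5, uniform_dist, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("family", ["uniform01", "exponential"])
    def test_monotone_in_G_and_ordered_in_eps(self, family):
        dist = DistributionSpec(family)
        grid = np.linspace(0.01, 0.99 if family == "uniform01" else 5.0, 50)
        prev = None
        for eps in (0, 1, 2, 5, 10):
            vals = np.array([peak_height_cdf(eps, dist, float(G)) for G in grid])
            assert np.all(np.diff(vals) >= 0)  # monotone in G
            if prev is not None:
                assert np.all(vals <= prev + 1e-12)  # larger eps -> smaller CDF
            prev = vals


class TestPeakHeightMoments:
    @pytest.mark.parametrize(
        "eps, mean, var",
        [(0, 1 / 2, 1 / 12), (4, 5 / 6, 5 / 252)],
    )
    def test_uniform(self, eps, mean, var, uniform_dist):
        m, v = peak_height_moments(eps, uniform_dist)
        assert m == pytest.approx(mean)
        assert v == pytest.approx(var)

    def test_exponential_unit_rate(self, exp_dist):
        m, v = peak_height_moments(1, exp_dist)
        assert m == pytest.approx(1.5)
        assert v == pytest.approx(1.25)

    def test_exponential_rate_scaling(self):
        m1, v1 = peak_height_moments(3, DistributionSpec("exponential", rate=1.0))
        m2, v2 = peak_height_moments(3, DistributionSpec("exponential", rate=2.0))
        assert m2 == pytest.approx(m1 / 2)
        assert v2 == pytest.approx(v1 / 4)


class TestAggregateCDF:
    def test_collapses_to_fitness_cdf_when_all_eps_zero(self, uniform_dist):
        g = _graph([(f"p{i}", 1) for i in range(4)], [])
        for G in (0.1, 0.5, 0.9):
            assert aggregate_peak_height_cdf(g, uniform_dist, G) == pytest.approx(G)

    def test_fibonacci_value(self, fib3_graph, uniform_dist):
        expected = (0.5**7 / 7 + 6 * 0.5**5 / 5) / (47 / 35)
        assert aggregate_peak_height_cdf(fib3_graph, uniform_dist, 0.5) == pytest.approx(expected)
        assert expected == pytest.approx(0.0288, abs=2e-4)

    def test_reaches_one_at_support_sup(self, fib3_graph, uniform_dist):
        assert aggregate_peak_height_cdf(fib3_graph, uniform_dist, 1.0) == pytest.approx(1.0)

    def test_vectorized_and_monotone(self, fib3_graph, exp_dist):
        grid = np.linspace(0, 8, 100)
        vals = aggregate_peak_height_cdf(fib3_graph, exp_dist, grid)
        assert vals.shape == grid.shape
        assert np.all(np.diff(vals) >= 0)


class TestSimulateTopography:
    def test_deterministic(self, fib3_graph, uniform_dist):
        a = simulate_topography(fib3_graph, uniform_dist, 50, seed=9)
        b = simulate_topography(fib3_graph, uniform_dist, 50, seed=9)
        assert np.array_equal(a.peak_counts, b.peak_counts)
        assert np.array_equal(a.ruggedness, b.ruggedness)

    def test_bounds_invariants(self, fib3_graph, uniform_dist):
        s = simulate_topography(fib3_graph, uniform_dist, 200, seed=4)
        assert np.all(s.peak_counts >= 1)
        assert np.all((s.ruggedness > 0) & (s.ruggedness <= 1))

    def test_mean_tracks_prediction(self, fib3_graph, uniform_dist):
        s = simulate_topography(fib3_graph, uniform_dist, 500, seed=2)
        se = s.peak_counts.std(ddof=1) / np.sqrt(len(s.peak_counts))
        assert abs(s.mean_peak_count - s.predicted_peak_count) < 3 * se


class TestRankInvariance:
    def test_monotone_transform_preserves_topography(self, fib3_graph, uniform_dist, exp_dist):
        """Peak sets, counts and ruggedness depend only on fitness ranks."""
        for seed in range(20):
            pf_u = draw_pf_map(fib3_graph.phenotypes + ["DELETERIOUS"], uniform_dist, seed)
            transformed = {
                p: (-np.log1p(-f) if p != "DELETERIOUS" else 0.0)
                for p, f in pf_u.fitness_of.items()
            }
            pf_e = PFMap(fitness_of=transformed, distribution=None)
            real_u = attach_fitness(fib3_graph, pf_u)
            real_e = attach_fitness(fib3_graph, pf_e)
            peaks_u = {p.nc_id for p in find_peaks(real_u)}
            peaks_e = {p.nc_id for p in find_peaks(real_e)}
            assert peaks_u == peaks_e
            assert ruggedness_of_realization(real_u) == ruggedness_of_realization(real_e)
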