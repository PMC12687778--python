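"""Kendall-tau machinery, graph filtering, hubs, layouts, composition."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from salnet import (
    CorrelationEdge,
    RegionSaliencyMatrix,
    ValidationError,
    composition_stats,
    filter_edges,
    hub_ranking,
    kendall_tau,
    pairwise_region_correlations,
    spring_layout,
    top_edges,
)


def brute_force_tau_b(x, y):
    """Independent oracle: exhaustive concordant/discordant pair counting
    with tie correction."""
    n = len(x)
    num = 0
    tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        sx = np.sign(x[j] - x[i])
        sy = np.sign(y[j] - y[i])
        num += sx * sy
        tx += sx == 0
        ty += sy == 0
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return num / denom if denom else float("nan")


class TestKendallTau:
    def test_perfect_concordance(self):
        tau, p = kendall_tau([1, 2, 3, 4], [1, 2, 3, 4])
        assert tau == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(4) * 1)  # only +-identity rank

    def test_perfect_discordance(self):
        tau, p = kendall_tau([1, 2, 3], [3, 2, 1])
        assert tau == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 6)

    def test_worked_pair_count_example(self):
        # 8 concordant, 2 discordant pairs of 10 -> tau = 0.6
        tau, _ = kendall_tau([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert tau == pytest.approx((8 - 2) / 10)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 9))
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            tau, p = kendall_tau(x, y)
            assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)
            assert 0.0 <= p <= 1.0

    def test_exact_p_matches_permutation_frequency(self, rng):
        # for a small vector the p-value is the exhaustive permutation tail
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        tau, p = kendall_tau(x, y)
        taus = [brute_force_tau_b(x, np.array(perm))
                for perm in itertools.permutations(y)]
        expect = np.mean([abs(t) >= abs(tau) - 1e-12 for t in taus])
        assert p == pytest.approx(expect)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            tau, p = kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(tau) and math.isnan(p)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            kendall_tau([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            kendall_tau([1, 2, np.nan], [1, 2, 3])


def _matrix(values, cortical=None, hemis=None, lobes=None):
    n_regions = values.shape[1]
    cortical = cortical if cortical is not None else [True] * n_regions
    hemis = hemis or ["L"] * n_regions
    lobes = lobes or ["frontal"] * n_regions
    regions = pd.DataFrame({
        "region_id": np.arange(1, n_regions + 1),
        "name": [f"r{i}" for i in range(n_regions)],
        "hemisphere": hemis,
        "lobe": lobes,
        "is_cortical": cortical,
        "network": ["Language"] * n_regions,
    })
    return RegionSaliencyMatrix(
        values=values,
        subject_ids=[f"s{i}" for i in range(len(values))],
        region_ids=regions["region_id"].to_numpy(),
        groups=["high"] * len(values),
        regions=regions,
    )


class TestPairwise:
    def test_candidate_pair_count_for_150_regions(self, rng):
        mat = _matrix(rng.random((12, 150)))
        edges = pairwise_region_correlations(mat, scope="cortical-cortical")
        assert len(edges) == 150 * 149 // 2 == 11175

    def test_identical_columns_have_tau_one(self, rng):
        vals = rng.random((10, 4))
        vals[:, 1] = vals[:, 0]
        edges = pairwise_region_correlations(_matrix(vals), scope="all")
        e = next(e for e in edges if (e.region_a, e.region_b) == (1, 2))
        assert e.tau == pytest.approx(1.0)

    def test_constant_column_skipped(self, rng):
        vals = rng.random((8, 4))
        vals[:, 2] = 7.0
        edges = pairwise_region_correlations(_matrix(vals), scope="all")
        assert all(3 not in (e.region_a, e.region_b) for e in edges)
        assert len(edges) == 3  # pairs among the remaining 3 columns

    def test_scope_restricts_pairs(self, rng):
        vals = rng.random((10, 5))
        cort = [True, True, True, False, False]
        edges = pairwise_region_correlations(_matrix(vals, cortical=cort),
                                             scope="cortical-subcortical")
        pairs = {(e.region_a, e.region_b) for e in edges}
        assert (1, 2) not in pairs  # cortical-cortical excluded
        assert (4, 5) in pairs      # subcortical-subcortical included
        assert (1, 4) in pairs      # cortico-subcortical included


EDGES = [
    CorrelationEdge(1, 2, 0.9, 1e-5),
    CorrelationEdge(1, 3, 0.5, 0.005),
    CorrelationEdge(2, 3, 0.45, 0.02),   # not significant at 0.01
    CorrelationEdge(2, 4, 0.2, 1e-4),    # below tau threshold 0.4
    CorrelationEdge(3, 4, -0.6, 1e-6),   # negative
]


class TestFilterAndTop:
    def test_hand_filtered_edge_set(self):
        g = filter_edges(EDGES, alpha=0.01, tau_threshold=0.4)
        kept = {(e.region_a, e.region_b) for e in g.edges}
        assert kept == {(1, 2), (1, 3)}
        assert g.degrees == {1: 2, 2: 1, 3: 1}

    def test_absolute_mode_keeps_negative_edges(self):
        g = filter_edges(EDGES, alpha=0.01, tau_threshold=0.4, absolute=True)
        kept = {(e.region_a, e.region_b) for e in g.edges}
        assert (3, 4) in kept

    def test_threshold_one_keeps_nothing(self):
        assert filter_edges(EDGES, tau_threshold=1.0).n_edges() == 0

    def test_edge_count_monotone_in_threshold(self, rng):
        vals = rng.random((15, 12))
        edges = pairwise_region_correlations(_matrix(vals), scope="all")
        counts = [filter_edges(edges, alpha=0.5, tau_threshold=t).n_edges()
                  for t in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_top_edges_sorted_and_complete_when_few(self):
        out = top_edges(EDGES, n=500)
        assert len(out) == 5
        taus = [e.tau for e in out]
        assert taus == sorted(taus, reverse=True)

    def test_top_edges_tie_break_is_deterministic(self):
        tied = [CorrelationEdge(1, 2, 0.5, 0.002),
                CorrelationEdge(1, 3, 0.5, 0.001),
                CorrelationEdge(2, 3, 0.5, 0.002)]
        for _ in range(5):
            out = top_edges(list(reversed(tied)), n=2)
            assert [(e.region_a, e.region_b) for e in out] == [(1, 3), (1, 2)]


class TestSpringLayout:
    def _graph(self, edges, n_regions, rng):
        mat = _matrix(rng.random((4, n_regions)))
        g = filter_edges(edges, alpha=1.0, tau_threshold=0.0, matrix=mat)
        return g

    def test_same_seed_reproduces_coordinates(self, rng):
        g = self._graph(EDGES, 4, rng)
        a = spring_layout(g, seed=3)
        b = spring_layout(g, seed=3)
        assert a == b

    def test_strong_pair_sits_closer_than_weak_path(self, rng):
        pair = self._graph([CorrelationEdge(1, 2, 0.95, 1e-4)], 2, rng)
        path = self._graph([CorrelationEdge(1, 2, 0.05, 1e-4),
                            CorrelationEdge(2, 3, 0.05, 1e-4)], 3, rng)
        d_pair = np.hypot(*(np.array(spring_layout(pair, seed=0)[1])
                            - np.array(spring_layout(pair, seed=0)[2])))
        coords = spring_layout(path, seed=0)
        d_path = min(np.hypot(*(np.array(coords[a]) - np.array(coords[b])))
                     for a, b in [(1, 2), (2, 3)])
        assert d_pair < d_path

    def test_isolated_node_sits_at_the_periphery(self, rng):
        g = self._graph([CorrelationEdge(1, 2, 0.8, 1e-4),
                         CorrelationEdge(2, 3, 0.8, 1e-4),
                         CorrelationEdge(1, 3, 0.8, 1e-4)], 4, rng)
        coords = spring_layout(g, seed=1)
        centroid = np.mean([coords[i] for i in (1, 2, 3)], axis=0)
        r_conn = max(np.linalg.norm(np.array(coords[i]) - centroid)
                     for i in (1, 2, 3))
        r_iso = np.linalg.norm(np.array(coords[4]) - centroid)
        assert r_iso > r_conn

    def test_empty_graph_rejected(self):
        import networkx as nx
        from salnet.corrnet import CorrelationGraph
        with pytest.raises(ValidationError):
            spring_layout(CorrelationGraph(nx.Graph(), 0.01, 0.4), seed=0)


class TestHubRanking:
    def test_default_sweep_divisor_is_six(self, rng):
        mat = _matrix(rng.random((12, 6)))
        hubs = hub_ranking(mat)
        assert hubs["divisor"] == 6

    def test_region_in_top_n_at_every_threshold_averages_its_degree(self):
        # two identical columns: tau = 1 edge survives every threshold
        base = np.arange(10.0)
        vals = np.c_[base, base, base[::-1] * 0 + np.arange(10) % 3]
        hubs = hub_ranking(_matrix(vals), thresholds=(0.1, 0.4, 0.6), top_n=3)
        row = next(r for r in hubs["averaged"] if r["region_id"] == 1)
        assert row["average_degree"] == pytest.approx(1.0)  # degree 1 at all 3

    def test_toy_matrix_matches_hand_enumeration(self):
        # 4 regions, 6 subjects; taus known by construction
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = a.copy()                      # tau(a,b) = 1
        c = np.array([1.0, 2, 3, 4, 6, 5])  # tau = 13/15
        d = np.array([6.0, 5, 4, 3, 2, 1])  # tau = -1 with a
        vals = np.c_[a, b, c, d]
        hubs = hub_ranking(_matrix(vals), thresholds=(0.5, 0.9), top_n=4,
                           alpha=0.05)
        # alpha 0.05 exact-p: |tau|=1 -> p=2/720; tau=13/15 -> p=4/720
        per = hubs["per_threshold"]
        deg_05 = {r["region_id"]: r["degree"] for r in per[0.5]}
        deg_09 = {r["region_id"]: r["degree"] for r in per[0.9]}
        assert deg_05 == {1: 2, 2: 2, 3: 2, 4: 0}
        assert deg_09 == {1: 1, 2: 1, 3: 0, 4: 0}
        avg = {r["region_id"]: r["average_degree"] for r in hubs["averaged"]}
        assert avg[1] == pytest.approx((2 + 1) / 2)
        assert avg[3] == pytest.approx(2 / 2)

    def test_thresholds_must_increase(self, rng):
        mat = _matrix(rng.random((8, 4)))
        with pytest.raises(ValidationError):
            hub_ranking(mat, thresholds=(0.4, 0.2))


class TestComposition:
    def _graph(self, edges, hemis, lobes, cortical, rng):
        mat = _matrix(rng.random((4, len(hemis))), cortical=cortical,
                      hemis=hemis, lobes=lobes)
        return filter_edges(edges, alpha=1.0, tau_threshold=0.0, matrix=mat)

    def test_all_edges_within_one_lobe(self, rng):
        g = self._graph([CorrelationEdge(1, 2, 0.5, 0.001)],
                        ["L", "L"], ["frontal", "frontal"], [True, True], rng)
        comp = composition_stats(g)
        assert comp["within_lobe_fraction"] == 1.0
        assert comp["lobe_fractions"] == {"L-frontal": 1.0}

    def test_hand_built_graph_tally(self, rng):
        hemis = ["L", "L", "R", "R", "L", "midline"]
        lobes = ["frontal", "frontal", "frontal", "temporal", "subcortical",
                 "subcortical"]
        cortical = [True, True, True, True, False, False]
        edges = [
            CorrelationEdge(1, 2, 0.5, 1e-3),  # within L-frontal
            CorrelationEdge(1, 3, 0.5, 1e-3),  # cross hemisphere
            CorrelationEdge(3, 4, 0.5, 1e-3),  # within R, cross lobe
            CorrelationEdge(1, 5, 0.5, 1e-3),  # LH cortex - subcortical
            CorrelationEdge(2, 5, 0.5, 1e-3),  # LH cortex - subcortical
            CorrelationEdge(4, 5, 0.5, 1e-3),  # RH cortex - subcortical
            CorrelationEdge(5, 6, 0.5, 1e-3),  # within subcortical
        ]
        comp = composition_stats(self._graph(edges, hemis, lobes, cortical, rng))
        assert comp["n_edges"] == 7
        assert comp["within_lobe_fraction"] == pytest.approx(1 / 7)
        att = comp["subcortical_attachment"]
        assert att["L"] == pytest.approx(2 / 4)
        assert att["R"] == pytest.approx(1 / 4)
        assert att["subcortical"] == pytest.approx(1 / 4)
        hf = comp["hemisphere_fractions"]
        assert hf["L"] + hf["R"] + hf["cross"] == pytest.approx(1.0)

    def test_empty_graph_reports_undefined_not_zero(self, rng):
        g = self._graph([], ["L", "R"], ["frontal", "frontal"], [True, True], rng)
        comp = composition_stats(g)
        assert comp["within_lobe_fraction"] is None
        assert comp["hemisphere_fractions"] is None
        assert comp["subcortical_attachment"] is None
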