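"""Cost graph construction, shortest paths, clustering, exemplar selection."""

import itertools

import numpy as np
import pytest

import atlasfuse as af
from atlasfuse.errors import ValidationError
from atlasfuse.graph import AtlasGraph, reconstruct_path
from atlasfuse.similarity import CostWeights


def graph_from_cost(cost, ids=None):
    cost = np.asarray(cost, dtype=float)
    n = cost.shape[0]
    ids = ids or [chr(ord("A") + i) for i in range(n - 1)] + ["T"]
    nanm = np.full_like(cost, np.nan)
    return AtlasGraph(ids, cost, nanm, nanm, nanm, nanm, CostWeights())


def brute_force_paths(cost, path_cost):
    """Enumerate every simple path; aggregate by sum or max."""
    n = cost.shape[0]
    agg = (lambda es: sum(es)) if path_cost == "additive" else (lambda es: max(es))
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for r in range(n - 1):
                for mids in itertools.permutations([v for v in range(n) if v not in (i, j)], r):
                    nodes = (i, *mids, j)
                    edges = [cost[a, b] for a, b in zip(nodes, nodes[1:])]
                    if all(np.isfinite(e) for e in edges):
                        dist[i, j] = min(dist[i, j], agg(edges))
    return dist


class TestFloydWarshall:
    def test_additive_two_hop_beats_direct(self):
        inf = np.inf
        cost = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.3], [inf, inf, 0.0]])
        pt = af.floyd_warshall(graph_from_cost(cost), path_cost="additive")
        assert pt.dist[0, 2] == pytest.approx(0.5)
        assert reconstruct_path(pt, 0, 2) == [0, 1, 2]

    def test_bottleneck_path_cost_is_worst_edge(self):
        inf = np.inf
        cost = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.3], [inf, inf, 0.0]])
        pt = af.floyd_warshall(graph_from_cost(cost), path_cost="bottleneck")
        assert pt.dist[0, 2] == pytest.approx(0.3)

    def test_self_distance_zero(self, rng):
        cost = rng.uniform(0, 1, size=(6, 6))
        pt = af.floyd_warshall(graph_from_cost(cost))
        assert np.all(np.diag(pt.dist) == 0)

    @pytest.mark.parametrize("path_cost", ["additive", "bottleneck"])
    def test_matches_enumeration_on_random_digraphs(self, path_cost):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 7))
            cost = rng.uniform(0, 1, size=(n, n))
            cost[rng.uniform(size=(n, n)) < 0.3] = np.inf  # sparsify
            np.fill_diagonal(cost, 0.0)
            pt = af.floyd_warshall(graph_from_cost(cost, ids=[str(i) for i in range(n)]), path_cost)
            oracle = brute_force_paths(cost, path_cost)
            assert np.allclose(pt.dist, oracle, equal_nan=True)

    def test_reconstructed_paths_achieve_distance(self, rng):
        cost = rng.uniform(0, 1, size=(6, 6))
        np.fill_diagonal(cost, 0.0)
        pt = af.floyd_warshall(graph_from_cost(cost), path_cost="additive")
        for i in range(6):
            for j in range(6):
                nodes = reconstruct_path(pt, i, j)
                total = sum(cost[a, b] for a, b in zip(nodes, nodes[1:]))
                assert total == pytest.approx(pt.dist[i, j], abs=1e-12)

    def test_negative_edges_rejected(self):
        cost = np.array([[0.0, -0.1], [0.2, 0.0]])
        with pytest.raises(ValidationError, match="negative"):
            af.floyd_warshall(graph_from_cost(cost, ids=["A", "T"]))


class TestClustering:
    def test_shared_vertex_merges(self):
        # P(A)=A->B->T (additive: 0.2+0.3 < 0.9), P(B)=B->T, P(C)=C->T
        inf = np.inf
        cost = np.array(
            [
                [0.0, 0.2, 0.9, 0.9],
                [0.2, 0.0, 0.9, 0.3],
                [0.9, 0.9, 0.0, 0.4],
                [inf, inf, inf, 0.0],
            ]
        )
        g = graph_from_cost(cost)
        pt = af.floyd_warshall(g, path_cost="additive")
        clusters = af.cluster_atlases(pt, g)
        assert clusters == [["A", "B"], ["C"]]

    def test_all_direct_paths_give_singletons(self):
        inf = np.inf
        cost = np.array(
            [
                [0.0, 0.9, 0.9, 0.1],
                [0.9, 0.0, 0.9, 0.2],
                [0.9, 0.9, 0.0, 0.3],
                [inf, inf, inf, 0.0],
            ]
        )
        g = graph_from_cost(cost)
        pt = af.floyd_warshall(g, path_cost="additive")
        assert af.cluster_atlases(pt, g) == [["A"], ["B"], ["C"]]

    def test_transitive_closure_through_shared_hub(self):
        # P(A)=A->B->T and P(C)=C->B->T -> one cluster {A, B, C}
        inf = np.inf
        cost = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.9, 0.0, 0.9, 0.2],
                [0.9, 0.1, 0.0, 0.9],
                [inf, inf, inf, 0.0],
            ]
        )
        g = graph_from_cost(cost)
        pt = af.floyd_warshall(g, path_cost="additive")
        assert af.cluster_atlases(pt, g) == [["A", "B", "C"]]

    def test_unreachable_atlas_rejected(self):
        inf = np.inf
        cost = np.array([[0.0, inf, inf], [inf, 0.0, 0.3], [inf, inf, 0.0]])
        g = graph_from_cost(cost)
        pt = af.floyd_warshall(g)
        with pytest.raises(ValidationError, match="reach"):
            af.cluster_atlases(pt, g)


class TestSelection:
    def _graph(self):
        inf = np.inf
        # cluster {A, B}: A routes through B; C is a singleton
        cost = np.array(
            [
                [0.0, 0.2, 0.9, 0.9],
                [0.2, 0.0, 0.9, 0.3],
                [0.9, 0.9, 0.0, 0.4],
                [inf, inf, inf, 0.0],
            ]
        )
        return graph_from_cost(cost)

    def test_exemplar_is_closest_with_direct_edge_weight(self):
        g = self._graph()
        pt = af.floyd_warshall(g, path_cost="additive")
        sel = af.select_exemplars(af.cluster_atlases(pt, g), pt, g)
        assert sel.exemplars == ["B", "C"]
        assert sel.weights[0] == pytest.approx(1.0 - 0.3)
        assert sel.weights[1] == pytest.approx(1.0 - 0.4)

    def test_tie_breaks_to_smallest_index(self):
        inf = np.inf
        cost = np.array(
            [[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [inf, inf, 0.0]]
        )
        g = graph_from_cost(cost)
        pt = af.floyd_warshall(g, path_cost="additive")
        clusters = [["A", "B"]]
        sel = af.select_exemplars(clusters, pt, g)
        assert sel.exemplars == ["A"]

    def test_weights_clamped_to_unit_interval(self):
        g = self._graph()
        pt = af.floyd_warshall(g, path_cost="additive")
        sel = af.select_exemplars(af.cluster_atlases(pt, g), pt, g)
        assert all(0.0 <= w <= 1.0 for w in sel.weights)


class TestBuildGraph:
    def test_identical_images_zero_fields_give_zero_costs(self, rng):
        img = af.VolumeImage(rng.uniform(0, 10, size=(8, 8, 8)))
        zero = af.DisplacementField(np.zeros((8, 8, 8, 3)))
        ids = ["a0", "a1"]
        regs = {}
        for a in ids:
            for b in ids + ["subject"]:
                if a != b:
                    regs[(a, b)] = af.RegistrationResult(zero, a, b)
        g = af.build_graph(img, [img, img], regs, atlas_ids=ids)
        finite = np.isfinite(g.cost)
        assert np.allclose(g.cost[finite], 0.0)

    def test_missing_registration_named(self, rng):
        img = af.VolumeImage(rng.uniform(size=(6, 6, 6)))
        zero = af.DisplacementField(np.zeros((6, 6, 6, 3)))
        regs = {("a0", "a1"): af.RegistrationResult(zero, "a0", "a1")}
        with pytest.raises(ValidationError, match=r"a1.*subject"):
            af.build_graph(img, [img, img], regs, atlas_ids=["a0", "a1"])

    def test_near_copy_atlas_cheaper_than_deformed_atlas(self):
        # atlas A: noisy copy of the subject (zero true field);
        # atlas B: heavily deformed -> cost(A->T) must undercut cost(B->T)
        img, _ = af.make_phantom(af.PhantomSpec(seed=11, noise_sd=0.0))
        rng = np.random.default_rng(11)
        subject = img
        a_img = af.VolumeImage(img.data + rng.normal(0, 1.0, img.shape))
        b_field = af.random_smooth_field(img.shape, 6.0, 4.0, seed=12)
        b_img = af.warp(img, b_field, "linear")
        zero = af.DisplacementField(np.zeros(img.shape + (3,)))
        b_inv = af.invert_field(b_field)
        regs = {
            ("A", "subject"): af.RegistrationResult(zero, "A", "subject"),
            ("B", "subject"): af.RegistrationResult(b_inv, "B", "subject"),
            ("A", "B"): af.RegistrationResult(b_field, "A", "B"),
            ("B", "A"): af.RegistrationResult(b_inv, "B", "A"),
        }
        g = af.build_graph(subject, [a_img, b_img], regs, atlas_ids=["A", "B"])
        t = g.subject_index
        assert g.cost[0, t] < g.cost[1, t]

    def test_subject_outgoing_edges_absent(self, default_population):
        pop, regs = default_population
        g = af.build_graph(pop.subject_image, [m[0] for m in pop.members], regs)
        t = g.subject_index
        off_diag = [j for j in range(g.n_nodes) if j != t]
        assert np.all(np.isinf(g.cost[t, off_diag]))
        assert g.cost[t, t] == 0.0
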