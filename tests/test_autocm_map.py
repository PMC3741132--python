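import itertools

import numpy as np
import pytest

from ocm_ann import autocm_map as am


def random_unit_matrix(rng, n=20, p=6):
    return rng.random((n, p))


def prufer_to_edges(sequence, n):
    """Decode a Prüfer sequence into the edge list of a labeled tree."""
    degree = [1] * n
    for node in sequence:
        degree[node] += 1
    edges = []
    seq = list(sequence)
    for node in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((leaf, node))
                degree[leaf] -= 1
                degree[node] -= 1
                break
    last = [i for i in range(n) if degree[i] == 1]
    edges.append((last[0], last[1]))
    return edges


def brute_force_mst_weight(d):
    """Exhaustive minimum over all labeled spanning trees (Prüfer enumeration)."""
    n = d.shape[0]
    if n == 2:
        return d[0, 1]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        weight = sum(d[i, j] for i, j in prufer_to_edges(seq, n))
        best = min(best, weight)
    return best


class TestTraining:
    def test_zero_input_is_fixed_point(self):
        x = np.zeros((1, 4))
        model = am.train_autocm(x, max_epochs=50)
        init = 0.01 * model.C
        np.testing.assert_array_equal(model.v, np.full(4, init))
        np.testing.assert_array_equal(model.w, np.full((4, 4), init))
        assert all(t == 0.0 for t in model.delta_trace)

    def test_convergence_and_saturation(self, rng):
        x = random_unit_matrix(rng)
        model = am.train_autocm(x, max_epochs=5000, tolerance=1e-6)
        assert model.converged
        # trace tail is decreasing after the initial growth phase
        tail = model.delta_trace[-10:]
        assert all(a >= b for a, b in zip(tail, tail[1:]))
        # active variables saturate toward C
        assert np.all(model.v / model.C > 0.99)

    def test_weight_bounds(self, rng):
        x = random_unit_matrix(rng, 30, 8)
        model = am.train_autocm(x)
        assert np.all(model.v >= 0) and np.all(model.v <= model.C)
        assert np.all(model.w >= 0) and np.all(model.w <= model.C)
        assert model.w.shape == (8, 8)

    @pytest.mark.parametrize("seed", range(5))
    def test_identical_columns_bind_strongest(self, seed):
        rng = np.random.default_rng(seed)
        x = random_unit_matrix(rng, 20, 6)
        x[:, 4] = x[:, 2]
        model = am.train_autocm(x)
        sym = (model.w + model.w.T) / 2
        paired = sym[2, 4]
        others = [sym[2, k] for k in range(6) if k not in (2, 4)]
        assert all(paired >= other for other in others)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            am.train_autocm(np.array([[0.5, 1.5]]))
        with pytest.raises(ValueError, match="C must be > 0"):
            am.train_autocm(np.array([[0.5, 0.5]]), C=-1.0)
        with pytest.raises(ValueError, match="2-D"):
            am.train_autocm(np.array([0.5, 0.5]))


class TestDistances:
    def test_formula_limits(self):
        model = am.AutoCMModel(
            C=4.0, v=np.full(3, 4.0), w=np.full((3, 3), 4.0),
            epochs=1, delta_trace=[0.0], converged=True,
        )
        d = am.weights_to_distances(model)
        assert np.all(d == 0.0)  # maximal weight -> zero distance

        model.w = np.zeros((3, 3))
        d = am.weights_to_distances(model)
        off = d[~np.eye(3, dtype=bool)]
        assert np.all(off == 4.0)
        assert np.all(np.diag(d) == 0.0)

    def test_monotone_in_weight(self, rng):
        x = random_unit_matrix(rng, 25, 5)
        model = am.train_autocm(x)
        d = am.weights_to_distances(model)
        sym = (model.w + model.w.T) / 2
        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        for a, b in itertools.combinations(pairs, 2):
            if sym[a] > sym[b]:
                assert d[a] < d[b]

    def test_untrained_model_rejected(self):
        model = am.AutoCMModel(
            C=2.0, v=np.zeros(2), w=np.zeros((2, 2)),
            epochs=0, delta_trace=[], converged=False, trained=False,
        )
        with pytest.raises(ValueError, match="not trained"):
            am.weights_to_distances(model)

    def test_symmetry_and_nonnegativity(self, rng):
        x = random_unit_matrix(rng, 15, 7)
        model = am.train_autocm(x)
        d = am.weights_to_distances(model)
        np.testing.assert_allclose(d, d.T)
        assert np.all(d >= 0)


class TestMST:
    def test_three_node_example(self):
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        edges = am.minimum_spanning_tree(d)
        assert [(i, j) for i, j, _ in edges] == [(0, 1), (1, 2)]

    def test_tree_properties(self, rng):
        import networkx as nx

        d = rng.random((12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        edges = am.minimum_spanning_tree(d)
        assert len(edges) == 11
        g = nx.Graph((i, j) for i, j, _ in edges)
        assert nx.is_tree(g)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            kruskal = sum(w for _, _, w in am.minimum_spanning_tree(d))
            assert kruskal == pytest.approx(brute_force_mst_weight(d))

    def test_deterministic_tie_break(self):
        d = np.ones((4, 4)) - np.eye(4)  # all ties
        edges = am.minimum_spanning_tree(d)
        assert [(i, j) for i, j, _ in edges] == [(0, 1), (0, 2), (0, 3)]

    def test_error_conditions(self):
        with pytest.raises(ValueError, match="finite"):
            am.minimum_spanning_tree(np.array([[0.0, np.inf], [np.inf, 0.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            am.minimum_spanning_tree(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestBuildMap:
    @pytest.fixture
    def trained(self, rng):
        x = random_unit_matrix(rng, 20, 6)
        model = am.train_autocm(x)
        d = am.weights_to_distances(model)
        mst = am.minimum_spanning_tree(d)
        names = [f"v{i}" for i in range(6)]
        return model, d, mst, names

    def test_link_strengths_in_unit_interval(self, trained):
        model, d, mst, names = trained
        cmap = am.build_map(model, d, mst, names)
        strengths = [ls for _, _, ls in cmap.mst_edges]
        assert all(0.0 <= ls <= 1.0 for ls in strengths)

    def test_strongest_pair_scores_one(self, trained):
        model, d, mst, names = trained
        cmap = am.build_map(model, d, mst, names)
        # the globally strongest pair has the smallest distance, so Kruskal
        # always admits it -> some edge carries ls = 1
        assert max(ls for _, _, ls in cmap.mst_edges) == pytest.approx(1.0)

    def test_star_mst_single_hub(self):
        p = 5
        w = np.zeros((p, p))
        w[0, 1:] = w[1:, 0] = 3.0  # node 0 strongly tied to everyone
        model = am.AutoCMModel(C=4.0, v=np.full(p, 4.0), w=w,
                               epochs=1, delta_trace=[0.0], converged=True)
        d = am.weights_to_distances(model)
        mst = am.minimum_spanning_tree(d)
        cmap = am.build_map(model, d, mst, [f"n{i}" for i in range(p)])
        assert cmap.hubs == ["n0"]
        assert sorted(cmap.neighbors("n0")) == ["n1", "n2", "n3", "n4"]

    def test_hub_set_invariant_under_relabeling(self, rng):
        x = random_unit_matrix(rng, 20, 6)
        names = [f"v{i}" for i in range(6)]
        model = am.train_autocm(x)
        d = am.weights_to_distances(model)
        cmap = am.build_map(model, d, am.minimum_spanning_tree(d), names)

        perm = np.random.default_rng(0).permutation(6)
        x_perm = x[:, perm]
        names_perm = [names[i] for i in perm]
        model_p = am.train_autocm(x_perm)
        d_p = am.weights_to_distances(model_p)
        cmap_p = am.build_map(model_p, d_p, am.minimum_spanning_tree(d_p), names_perm)
        assert set(cmap.hubs) == set(cmap_p.hubs)


class TestExport:
    @pytest.fixture
    def cmap(self, rng):
        x = random_unit_matrix(rng, 20, 6)
        model = am.train_autocm(x)
        d = am.weights_to_distances(model)
        mst = am.minimum_spanning_tree(d)
        return am.build_map(model, d, mst, [f"v{i}" for i in range(6)])

    def test_graphml_round_trip(self, cmap):
        text = am.export_map(cmap, "graphml")
        back = am.import_graphml(text)
        assert set(back.nodes) == set(cmap.nodes)
        original = {frozenset((a, b)): ls for a, b, ls in cmap.mst_edges}
        recovered = {frozenset((a, b)): ls for a, b, ls in back.mst_edges}
        assert original.keys() == recovered.keys()
        for key in original:
            assert recovered[key] == pytest.approx(original[key], abs=1e-9)
        assert set(back.hubs) == set(cmap.hubs)

    def test_dot_output_structure(self, cmap):
        text = am.export_map(cmap, "dot")
        assert text.startswith("graph connectivity_map {")
        assert text.rstrip().endswith("}")
        for a, b, ls in cmap.mst_edges:
            assert f'"{a}" -- "{b}" [label="{ls:.2f}"];' in text

    def test_edge_labels_two_decimals(self, cmap):
        import re

        text = am.export_map(cmap, "dot")
        labels = re.findall(r'label="([\d.]+)"', text)
        assert len(labels) == len(cmap.mst_edges)
        assert all(re.fullmatch(r"\d\.\d\d", s) for s in labels)

    def test_unknown_format_rejected(self, cmap):
        with pytest.raises(ValueError, match="unknown format"):
            am.export_map(cmap, "gexf")

    def test_write_map_files(self, cmap, tmp_path):
        paths = am.write_map(cmap, tmp_path)
        assert sorted(p.name for p in paths) == [
            "distances.csv", "map.dot", "map.graphml", "mst_edges.csv",
        ]
        for p in paths:
            assert p.exists() and p.stat().st_size > 0
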