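import math

import numpy as np
import pytest
from scipy import ndimage

from fibrekit import (
    Fibre,
    FibreNetwork,
    FireParams,
    extract_network,
    fibre_metrics,
    identify_fibres,
    network_metrics,
)
from fibrekit.fibre_network import read_network, write_network


def draw_line(shape, start, end, width=1):
    """Rasterize a straight stroke and blur it softly."""
    img = np.zeros(shape)
    n = int(max(abs(end[0] - start[0]), abs(end[1] - start[1]))) + 1
    rr = np.round(np.linspace(start[0], end[0], n)).astype(int)
    cc = np.round(np.linspace(start[1], end[1], n)).astype(int)
    img[rr, cc] = 1.0
    if width > 1:
        img = ndimage.binary_dilation(img > 0, iterations=width - 1).astype(float)
    return ndimage.gaussian_filter(img, 1.0)


def path_network(points):
    """A simple path-graph network through the given positions."""
    nodes = np.asarray(points, dtype=float)
    return FibreNetwork(nodes=nodes, edges=[(i, i + 1) for i in range(len(nodes) - 1)])


class TestExtractNetwork:
    def test_blank_raster_gives_empty_network(self):
        net = extract_network(np.zeros((64, 64)), FireParams(intensity_threshold=0.5))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_straight_line_traced_over_90_percent(self, line_raster):
        net = extract_network(line_raster, FireParams())
        fibres, _ = identify_fibres(net)
        assert len(fibres) >= 1
        longest = max(fibres, key=lambda f: f.length)
        drawn = 200 * math.sqrt(2)
        assert longest.length >= 0.9 * drawn
        assert longest.waviness > 0.98

    def test_crossing_lines_fuse_with_junction(self):
        img = draw_line((256, 256), (20, 20), (220, 220), width=2) + draw_line(
            (256, 256), (220, 20), (20, 220), width=2
        )
        net = extract_network(img, FireParams())
        g = net.to_graph()
        import networkx as nx

        assert nx.number_connected_components(g) == 1
        assert any(g.degree(n) >= 3 for n in g.nodes)

    def test_disjoint_curves_give_one_fibre_each(self):
        img = (
            draw_line((256, 256), (40, 20), (40, 230), width=2)
            + draw_line((256, 256), (128, 20), (128, 230), width=2)
            + draw_line((256, 256), (210, 20), (210, 230), width=2)
        )
        net = extract_network(img, FireParams())
        fibres, _ = identify_fibres(net)
        assert len(fibres) == 3

    def test_translation_equivariance(self):
        base = draw_line((256, 256), (60, 60), (160, 160), width=2)
        shifted = np.roll(base, (30, 30), axis=(0, 1))
        n0 = extract_network(base, FireParams())
        n1 = extract_network(shifted, FireParams())
        assert abs(n0.n_nodes - n1.n_nodes) <= 2
        c0 = n0.nodes.mean(axis=0)
        c1 = n1.nodes.mean(axis=0)
        np.testing.assert_allclose(c1 - c0, [30, 30], atol=3)

    def test_threshold_monotonicity(self, line_raster):
        counts = [
            extract_network(line_raster, FireParams(intensity_threshold=t)).n_nodes
            for t in (0.1, 0.3, 0.5, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_deterministic(self, line_raster):
        a = extract_network(line_raster, FireParams())
        b = extract_network(line_raster, FireParams())
        np.testing.assert_array_equal(a.nodes, b.nodes)
        assert a.edges == b.edges

    def test_invariants_hold(self, line_raster):
        params = FireParams()
        net = extract_network(line_raster, params)
        assert len(set(net.edges)) == len(net.edges)
        assert all(u != v for u, v in net.edges)
        assert all(net.edge_length(u, v) <= params.edge_threshold + 1e-9 for u, v in net.edges)


class TestIdentifyFibres:
    def test_path_graph_traced_once(self):
        net = path_network([(0, 0), (0, 3), (0, 6)])
        fibres, cycles = identify_fibres(net)
        assert len(fibres) == 1
        assert len(fibres[0].path) == 3
        assert cycles == []

    def test_y_graph_collinear_branch_gives_two_fibres(self):
        # junction at origin: collinear main branch along the column axis,
        # third tip heading off at 90 degrees
        nodes = [(0.0, -4.0), (0.0, 0.0), (0.0, 4.0), (4.0, 0.0)]
        net = FibreNetwork(
            nodes=np.asarray(nodes), edges=[(0, 1), (1, 2), (1, 3)]
        )
        fibres, _ = identify_fibres(net, angle_tol=70.0)
        assert len(fibres) == 2
        lengths = sorted(f.length for f in fibres)
        assert lengths == [4.0, 8.0]  # the stub and the straight-through fibre

    def test_cycle_without_tip_goes_to_residual(self):
        nodes = [(0.0, 0.0), (0.0, 3.0), (3.0, 0.0)]
        net = FibreNetwork(nodes=np.asarray(nodes), edges=[(0, 1), (0, 2), (1, 2)])
        fibres, cycles = identify_fibres(net)
        assert fibres == []
        assert cycles == [[0, 1, 2]]

    def test_no_edge_reused_across_fibres(self, line_raster):
        net = extract_network(line_raster, FireParams())
        fibres, _ = identify_fibres(net)
        used = sum(len(f.path) - 1 for f in fibres)
        assert used <= net.n_edges


class TestFibreMetrics:
    def test_straight_fibre_345(self):
        f = Fibre.from_path([0, 1], np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert f.length == 5.0
        assert f.displacement == 5.0
        assert f.waviness == 1.0

    def test_semicircle_waviness_two_over_pi(self):
        theta = np.linspace(0, np.pi, 500)
        pts = np.column_stack([np.sin(theta), -np.cos(theta)]) * 100.0
        f = Fibre.from_path(list(range(500)), pts)
        assert f.waviness == pytest.approx(2 / np.pi, abs=1e-3)

    def test_straight_fibres_mean_waviness_one(self):
        fibres = [
            Fibre.from_path([0, 1], np.array([[0.0, 0.0], [float(k), float(k)]]))
            for k in (3, 5, 7)
        ]
        assert fibre_metrics(fibres)["mean_waviness"] == pytest.approx(1.0)

    def test_empty_list_gives_sentinels(self):
        m = fibre_metrics([])
        assert m["n_fibres"] == 0
        assert math.isnan(m["mean_waviness"]) and math.isnan(m["mean_length"])

    def test_repeated_node_rejected(self):
        with pytest.raises(ValueError):
            Fibre.from_path([0, 1, 0], np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestNetworkMetrics:
    def test_triangle_spectrum(self):
        nodes = np.array([[0.0, 0.0], [0.0, 3.0], [3.0, 0.0]])
        net = FibreNetwork(nodes=nodes, edges=[(0, 1), (0, 2), (1, 2)])
        m = network_metrics(net, [])
        assert m["degree"] == pytest.approx(2.0)
        assert m["max_eigenvalue"] == pytest.approx(2.0, abs=1e-9)
        assert m["connectivity"] == pytest.approx(3.0, abs=1e-9)

    def test_path_graph_p4_spectrum(self):
        net = path_network([(0, 0), (0, 3), (0, 6), (0, 9)])
        m = network_metrics(net, [])
        assert m["degree"] == pytest.approx(1.5)
        assert m["max_eigenvalue"] == pytest.approx(2 * math.cos(math.pi / 5), abs=1e-9)

    def test_star_s3_crosslink_density(self):
        nodes = np.array([[0.0, 0.0], [0.0, 4.0], [4.0, 0.0], [0.0, -4.0]])
        net = FibreNetwork(nodes=nodes, edges=[(0, 1), (0, 2), (0, 3)])
        fibres, _ = identify_fibres(net)
        m = network_metrics(net, fibres)
        assert m["crosslink_density"] == pytest.approx(1.0 / len(fibres))

    def test_node_connectivity_mode_on_triangle(self):
        nodes = np.array([[0.0, 0.0], [0.0, 3.0], [3.0, 0.0]])
        net = FibreNetwork(nodes=nodes, edges=[(0, 1), (0, 2), (1, 2)])
        m = network_metrics(net, [], connectivity_mode="node")
        assert m["connectivity"] == pytest.approx(2.0)  # K3 pairwise connectivity

    def test_empty_network_gives_sentinels(self):
        net = FibreNetwork(nodes=np.empty((0, 2)), edges=[])
        m = network_metrics(net, [])
        assert all(math.isnan(v) for v in m.values())


class TestNetworkIO:
    def test_edge_list_round_trip(self, tmp_path, line_raster):
        net = extract_network(line_raster, FireParams())
        path = tmp_path / "net.txt"
        write_network(net, path)
        back = read_network(path)
        np.testing.assert_allclose(back.nodes, net.nodes, atol=1e-3)
        assert back.edges == net.edges
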