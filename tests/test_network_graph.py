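import numpy as np
import pytest
from scipy import ndimage

from tidechan import network_graph as ng
from tidechan.scene_io import RasterGrid

from conftest import make_mask, random_tree_network, strahler_oracle

_EIGHT = ndimage.generate_binary_structure(2, 2)


class TestSkeletonize:
    def test_ribbon_thins_to_line(self):
        chan = np.zeros((9, 20), dtype=np.uint8)
        chan[3:6, 2:18] = 1
        skel = ng.skeletonize(make_mask(chan)).values.astype(bool)
        # 1-pixel wide: no pixel has a 2x2 block of skeleton
        assert not (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any()
        _, n = ndimage.label(skel, structure=_EIGHT)
        assert n == 1

    def test_empty(self):
        skel = ng.skeletonize(make_mask(np.zeros((5, 5))))
        assert not skel.values.any()

    def test_component_count_preserved(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            chan = (rng.random((40, 40)) < 0.25).astype(np.uint8)
            _, n_before = ndimage.label(chan, structure=_EIGHT)
            skel = ng.skeletonize(make_mask(chan)).values
            _, n_after = ndimage.label(skel, structure=_EIGHT)
            assert n_after == n_before


class TestBuildNetwork:
    def test_straight_line(self):
        sk = np.zeros((5, 15), dtype=np.uint8)
        sk[2, 2:13] = 1  # 11 pixels -> 10 steps
        net = ng.build_network(RasterGrid(sk, 3.0))
        assert len(net.edges) == 1
        assert ng.total_length(net) == pytest.approx(30.0)

    def test_diagonal_line(self):
        sk = np.zeros((15, 15), dtype=np.uint8)
        for i in range(11):
            sk[i, i] = 1
        net = ng.build_network(RasterGrid(sk, 1.0))
        assert ng.total_length(net) == pytest.approx(10 * np.sqrt(2))

    def test_y_shape(self, y_mask):
        net = ng.build_network(ng.skeletonize(y_mask))
        roles = [n.role for n in net.nodes.values()]
        assert len(net.edges) == 3
        assert roles.count("junction") == 1
        assert roles.count("endpoint") == 3

    def test_isolated_cycle_gets_artificial_node(self):
        # diamond ring: every pixel has exactly two 8-neighbors
        sk = np.zeros((9, 9), dtype=np.uint8)
        for r in range(9):
            for c in range(9):
                if abs(r - 4) + abs(c - 4) == 3:
                    sk[r, c] = 1
        net = ng.build_network(RasterGrid(sk, 1.0))
        assert len(net.nodes) == 1
        assert len(net.edges) == 1
        assert net.edges[0].length > 0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        chan = (rng.random((30, 30)) < 0.3).astype(np.uint8)
        skel = ng.skeletonize(make_mask(chan)).values
        l0 = ng.total_length(ng.build_network(RasterGrid(skel, 1.0)))
        l90 = ng.total_length(ng.build_network(RasterGrid(np.rot90(skel).copy(), 1.0)))
        assert l90 == pytest.approx(l0)


class TestOutlets:
    def test_bottom_edge_outlet(self, y_mask):
        net = ng.build_network(ng.skeletonize(y_mask))
        ng.identify_outlets(net, y_mask, "bottom")
        outs = net.outlets()
        assert len(outs) == 1
        # the outlet is the node nearest the bottom edge
        assert net.nodes[outs[0]].y == min(n.y for n in net.nodes.values())

    def test_interior_component_fallback(self):
        chan = np.zeros((30, 30), dtype=np.uint8)
        chan[5, 10:20] = 1  # far from the bottom edge
        mask = make_mask(chan)
        net = ng.build_network(ng.skeletonize(mask))
        ng.identify_outlets(net, mask, "bottom")
        assert len(net.outlets()) == 1

    def test_two_components_two_outlets(self):
        chan = np.zeros((20, 30), dtype=np.uint8)
        chan[10:20, 5] = 1
        chan[10:20, 25] = 1
        mask = make_mask(chan)
        net = ng.build_network(ng.skeletonize(mask))
        ng.identify_outlets(net, mask, "bottom")
        assert len(net.outlets()) >= 2

    def test_unknown_edge_rejected(self, y_mask):
        net = ng.build_network(ng.skeletonize(y_mask))
        with pytest.raises(ValueError):
            ng.identify_outlets(net, y_mask, "north")


class TestStrahler:
    def test_two_branches_make_order_two(self, y_mask):
        net = ng.build_network(ng.skeletonize(y_mask))
        ng.identify_outlets(net, y_mask, "bottom")
        ng.assign_strahler(net)
        orders = sorted(e.strahler_order for e in net.edges.values())
        assert orders == [1, 1, 2]

    def test_perfect_binary_tree_order(self):
        # 4 leaves joined pairwise -> outlet order 3
        net = ng.ChannelNetwork(1.0)
        root = net.add_node(0, 0, role="outlet")
        j = net.add_node(0, 1)
        net.add_edge(root, j, [(0, 0), (0, 1)], component_id=1)
        for sx in (-1.0, 1.0):
            jj = net.add_node(sx, 2)
            net.add_edge(j, jj, [(0, 1), (sx, 2)], component_id=1)
            for sx2 in (-0.5, 0.5):
                leaf = net.add_node(sx + sx2, 3)
                net.add_edge(jj, leaf, [(sx, 2), (sx + sx2, 3)], component_id=1)
        ng.assign_strahler(net)
        assert net.max_order() == 3

    def test_matches_recursive_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            net = random_tree_network(rng, n_nodes=int(rng.integers(3, 40)))
            ng.assign_strahler(net)
            expected = strahler_oracle(net, net.outlets()[0])
            got = {eid: e.strahler_order for eid, e in net.edges.items()}
            assert got == expected

    def test_outlet_order_log2_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            net = random_tree_network(rng, n_nodes=int(rng.integers(4, 60)))
            ng.assign_strahler(net)
            n_leaves = sum(
                1 for nid, n in net.nodes.items()
                if n.role == "endpoint" and len(net.incident()[nid]) == 1
            )
            assert net.max_order() <= int(np.ceil(np.log2(max(n_leaves, 1)))) + 1

    def test_cycle_broken_with_warning(self, caplog):
        net = ng.ChannelNetwork(1.0)
        a = net.add_node(0, 0, role="outlet")
        b = net.add_node(0, 1)
        c = net.add_node(1, 1)
        net.add_edge(a, b, [(0, 0), (0, 1)], component_id=1)
        net.add_edge(b, c, [(0, 1), (1, 1)], component_id=1)
        net.add_edge(c, a, [(1, 1), (0, 0)], component_id=1)
        with caplog.at_level("WARNING", logger="tidechan"):
            ng.assign_strahler(net)
        assert "cycle" in caplog.text
        assert all(e.strahler_order is not None for e in net.edges.values())


class TestPruneAndLength:
    def _ordered_y(self, y_mask):
        net = ng.build_network(ng.skeletonize(y_mask))
        ng.identify_outlets(net, y_mask, "bottom")
        return ng.assign_strahler(net)

    def test_total_length_sums(self):
        net = ng.ChannelNetwork(1.0)
        a, b, c = net.add_node(0, 0), net.add_node(30, 0), net.add_node(30, 40)
        net.add_edge(a, b, [(0, 0), (30, 0)])
        net.add_edge(b, c, [(30, 0), (30, 40)])
        assert ng.total_length(net) == pytest.approx(70.0)
        assert ng.total_length(ng.ChannelNetwork(1.0)) == 0.0

    def test_prune_zero_is_identity(self, y_mask):
        net = self._ordered_y(y_mask)
        pruned = ng.prune_orders(net, 0)
        assert ng.total_length(pruned) == pytest.approx(ng.total_length(net))
        assert len(pruned.edges) == len(net.edges)

    def test_prune_one_keeps_stem(self, y_mask):
        net = self._ordered_y(y_mask)
        pruned = ng.prune_orders(net, 1)
        assert len(pruned.edges) == 1
        assert next(iter(pruned.edges.values())).strahler_order == 2

    def test_length_monotone_in_r(self, y_mask):
        net = self._ordered_y(y_mask)
        lengths = [ng.total_length(ng.prune_orders(net, r)) for r in range(0, 3)]
        assert lengths[0] > lengths[1] > lengths[2] == 0.0
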