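"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's code paths: Strahler
orders by naive recursion, nearest-channel distances by exhaustive search,
rank-sum p-values from the symmetric-tail definition, and run counts by
itertools.groupby.
"""

from __future__ import annotations

import sys
from itertools import combinations, groupby
from math import comb, hypot

import numpy as np
import pytest

from tidechan.network_graph import ChannelNetwork
from tidechan.scene_io import ChannelMask, RasterGrid


# ---------------------------------------------------------------------------
# Mask helpers


def make_mask(channel: np.ndarray, pixel_size: float = 1.0, aoi=None) -> ChannelMask:
    channel = np.asarray(channel).astype(np.uint8)
    if aoi is None:
        aoi = np.ones_like(channel)
    return ChannelMask(
        RasterGrid(channel, pixel_size), RasterGrid(np.asarray(aoi).astype(np.uint8), pixel_size)
    )


@pytest.fixture
def y_mask() -> ChannelMask:
    """A Y-shaped channel: stem from the bottom edge splitting into two arms."""
    chan = np.zeros((20, 20), dtype=np.uint8)
    chan[10:20, 10] = 1
    for i in range(1, 9):
        chan[10 - i, 10 - i] = 1
        chan[10 - i, 10 + i] = 1
    return make_mask(chan)


# ---------------------------------------------------------------------------
# Random tree networks (vector) for Strahler testing


def random_tree_network(rng: np.random.Generator, n_nodes: int = 20) -> ChannelNetwork:
    """Random recursive tree as a vector ChannelNetwork, root marked outlet.

    Node coordinates are synthetic (index-based) and only need to give
    positive edge lengths.
    """
    net = ChannelNetwork(1.0)
    root = net.add_node(0.0, 0.0, role="outlet")
    nodes = [root]
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, len(nodes)))
        nid = net.add_node(float(i), float(rng.uniform(1.0, 5.0)))
        pa = net.nodes[nodes[parent]]
        nb = net.nodes[nid]
        net.add_edge(nodes[parent], nid, [(pa.x, pa.y), (nb.x, nb.y)], component_id=1)
        nodes.append(nid)
    for nid, node in net.nodes.items():
        if node.role != "outlet":
            node.role = "endpoint" if len(net.incident()[nid]) <= 1 else "junction"
    return net


def strahler_oracle(net: ChannelNetwork, root: int) -> dict[int, int]:
    """Leaf-to-root recursive Strahler orders, independent of the library."""
    sys.setrecursionlimit(10000)
    adj: dict[int, list[tuple[int, int]]] = {}
    for eid, e in net.edges.items():
        adj.setdefault(e.a, []).append((eid, e.b))
        adj.setdefault(e.b, []).append((eid, e.a))

    orders: dict[int, int] = {}

    def visit(eid: int, node: int) -> int:
        children = [(ce, cn) for ce, cn in adj.get(node, []) if ce != eid]
        if not children:
            orders[eid] = 1
        else:
            sub = sorted(visit(ce, cn) for ce, cn in children)
            if len(sub) >= 2 and sub[-1] == sub[-2]:
                orders[eid] = sub[-1] + 1
            else:
                orders[eid] = sub[-1]
        return orders[eid]

    for eid, child in adj.get(root, []):
        visit(eid, child)
    return orders


# ---------------------------------------------------------------------------
# Exhaustive nearest-channel oracle


def nearest_channel_oracle(channel: np.ndarray, seeds_by_id: dict[int, np.ndarray]):
    """All-pairs nearest-seed allocation: (distance, id) per pixel, ties to
    the smaller id. O(N * M), for small grids only."""
    shape = channel.shape
    dist = np.full(shape, np.inf)
    owner = np.zeros(shape, dtype=int)
    coords = {
        wid: np.argwhere(seeds_by_id[wid]) for wid in sorted(seeds_by_id)
    }
    for r in range(shape[0]):
        for c in range(shape[1]):
            best_d, best_id = np.inf, 0
            for wid in sorted(coords):
                pts = coords[wid]
                if not len(pts):
                    continue
                d = np.sqrt(((pts - (r, c)) ** 2).sum(axis=1)).min()
                if d < best_d - 1e-9:
                    best_d, best_id = d, wid
            dist[r, c] = best_d
            owner[r, c] = best_id
    return dist, owner


# ---------------------------------------------------------------------------
# Rank-sum enumeration oracle (symmetric-tail formulation)


def ranksum_exact_oracle(n1: int, n2: int, w: float) -> float:
    """P(|W - mu| >= |w - mu|) over all C(n1+n2, n1) rank assignments."""
    mu = n1 * (n1 + n2 + 1) / 2.0
    hits = 0
    for ranks in combinations(range(1, n1 + n2 + 1), n1):
        if abs(sum(ranks) - mu) >= abs(w - mu) - 1e-12:
            hits += 1
    return hits / comb(n1 + n2, n1)


# ---------------------------------------------------------------------------
# Run-length oracle


def run_count_oracle(line: np.ndarray, threshold: float, min_run: int = 2) -> int:
    flags = (np.asarray(line) <= -threshold).tolist()
    return sum(1 for key, grp in groupby(flags) if key and len(list(grp)) >= min_run)
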