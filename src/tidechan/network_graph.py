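"""Centerline graphs: skeletonization, tracing, Strahler orders, pruning.

The graph lives in world coordinates (meters); edge polylines follow pixel
centers of the skeleton, so step lengths are ``pixel_size`` for rook moves
and ``sqrt(2) * pixel_size`` for diagonal moves. Orders follow the Strahler
scheme: leaf channels are order 1 and the order increments below a junction
only when the maximum upstream order is attained by at least two branches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import skeletonize as _sk_skeletonize

from tidechan.scene_io import ChannelMask, RasterGrid

logger = logging.getLogger("tidechan")

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class Node:
    x: float
    y: float
    role: str = "junction"  # junction | endpoint | outlet


@dataclass
class Edge:
    a: int
    b: int
    points: list  # [(x, y), ...] pixel centers, world frame
    length: float
    strahler_order: int | None = None
    component_id: int = 0


@dataclass
class ChannelNetwork:
    """Measured centerline graph of a channel mask."""

    pixel_size: float = 1.0
    nodes: dict[int, Node] = field(default_factory=dict)
    edges: dict[int, Edge] = field(default_factory=dict)

    def add_node(self, x: float, y: float, role: str = "junction") -> int:
        nid = len(self.nodes)
        self.nodes[nid] = Node(float(x), float(y), role)
        return nid

    def add_edge(self, a, b, points, strahler_order=None, component_id=0) -> int:
        pts = [(float(x), float(y)) for x, y in points]
        length = sum(
            math.hypot(x1 - x0, y1 - y0) for (x0, y0), (x1, y1) in zip(pts, pts[1:])
        )
        if a == b and length == 0:
            raise ValueError("zero-length self-loop edges are not allowed")
        eid = len(self.edges)
        self.edges[eid] = Edge(a, b, pts, length, strahler_order, component_id)
        return eid

    # -- topology helpers ---------------------------------------------------

    def incident(self) -> dict[int, list[int]]:
        """node id -> incident edge ids (self-loops listed twice)."""
        inc: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for eid, e in self.edges.items():
            inc[e.a].append(eid)
            inc[e.b].append(eid)
        return inc

    def degree(self, nid: int) -> int:
        return len(self.incident()[nid])

    def component_ids(self) -> list[int]:
        return sorted({e.component_id for e in self.edges.values()})

    def edges_of_component(self, cid: int) -> list[int]:
        return [eid for eid, e in self.edges.items() if e.component_id == cid]

    def outlets(self) -> list[int]:
        return [nid for nid, n in self.nodes.items() if n.role == "outlet"]

    def copy(self) -> "ChannelNetwork":
        net = ChannelNetwork(self.pixel_size)
        net.nodes = {nid: Node(n.x, n.y, n.role) for nid, n in self.nodes.items()}
        net.edges = {
            eid: Edge(e.a, e.b, list(e.points), e.length, e.strahler_order, e.component_id)
            for eid, e in self.edges.items()
        }
        return net

    def max_order(self) -> int:
        orders = [e.strahler_order for e in self.edges.values() if e.strahler_order]
        return max(orders) if orders else 0


# ---------------------------------------------------------------------------
# Skeletonization


def skeletonize(mask: ChannelMask) -> RasterGrid:
    """Thin a binary channel mask to a 1-pixel-wide, 8-connected skeleton.

    Connectivity is preserved: the skeleton has the same number of
    8-connected components as the input mask.
    """
    chan = mask.channel
    skel = _sk_skeletonize(chan)
    # guard: thinning may erase 1-2 pixel specks entirely; restore a pixel
    lbl_in, k_in = ndimage.label(chan, structure=_EIGHT)
    _, k_out = ndimage.label(skel, structure=_EIGHT)
    if k_out < k_in:
        surviving = set(np.unique(lbl_in[skel])) - {0}
        for cid in range(1, k_in + 1):
            if cid not in surviving:
                rows, cols = np.nonzero(lbl_in == cid)
                skel[rows[0], cols[0]] = True
    return mask.grid.copy_with(skel.astype(np.uint8))


# ---------------------------------------------------------------------------
# Graph construction


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _EIGHT, mode="constant") - skel.astype(int)


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def build_network(skeleton: RasterGrid, pixel_size: float | None = None) -> ChannelNetwork:
    """Trace a 1-pixel skeleton into a node/edge graph with measured lengths.

    Nodes sit at skeleton pixels with != 2 skeleton neighbors
    (8-connectivity); edges are the degree-2 chains between them. Isolated
    cycles receive one artificial node.
    """
    ps = float(pixel_size if pixel_size is not None else skeleton.pixel_size)
    skel = skeleton.values.astype(bool)
    net = ChannelNetwork(ps)
    if not skel.any():
        return net

    nbrs = _neighbor_counts(skel)
    is_node = skel & (nbrs != 2)
    node_id = {}

    def world(rc):
        x, y = skeleton.pixel_to_world(rc[0], rc[1])
        return float(x), float(y)

    for rc in zip(*np.nonzero(is_node)):
        node_id[rc] = net.add_node(*world(rc))

    rows, cols = skel.shape

    def skel_neighbors(rc):
        r, c = rc
        out = []
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and skel[rr, cc]:
                out.append((rr, cc))
        return out

    chain_used = np.zeros_like(skel, dtype=bool)
    seen_pairs = set()

    for rc in sorted(node_id):
        for nb in skel_neighbors(rc):
            if nb in node_id:
                key = (min(rc, nb), max(rc, nb))
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                net.add_edge(node_id[rc], node_id[nb], [world(rc), world(nb)])
            else:
                if chain_used[nb]:
                    continue
                path = [rc, nb]
                chain_used[nb] = True
                prev, cur = rc, nb
                while cur not in node_id:
                    nxt = [p for p in skel_neighbors(cur) if p != prev]
                    if not nxt:  # dead-end chain pixel (shouldn't occur)
                        break
                    # at a degree-2 pixel there is exactly one way forward
                    prev, cur = cur, nxt[0]
                    path.append(cur)
                    if cur not in node_id:
                        chain_used[cur] = True
                if cur in node_id:
                    net.add_edge(node_id[rc], node_id[cur], [world(p) for p in path])

    # isolated cycles: every pixel degree 2, no node pixel
    remaining = skel & ~chain_used & ~is_node
    for rc in zip(*np.nonzero(remaining)):
        if chain_used[rc]:
            continue
        start = rc
        nid = net.add_node(*world(start))
        node_id[start] = nid
        path = [start]
        chain_used[start] = True
        prev, cur = start, skel_neighbors(start)[0]
        while cur != start:
            path.append(cur)
            chain_used[cur] = True
            nxt = [p for p in skel_neighbors(cur) if p != prev]
            prev, cur = cur, nxt[0]
        path.append(start)
        net.add_edge(nid, nid, [world(p) for p in path])

    _assign_components(net)
    _assign_roles(net)
    return net


def _assign_components(net: ChannelNetwork) -> None:
    parent = {nid: nid for nid in net.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in net.edges.values():
        ra, rb = find(e.a), find(e.b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(nid) for nid in net.nodes})
    cid_of_root = {r: i + 1 for i, r in enumerate(roots)}
    for e in net.edges.values():
        e.component_id = cid_of_root[find(e.a)]


def _assign_roles(net: ChannelNetwork) -> None:
    inc = net.incident()
    for nid, node in net.nodes.items():
        if node.role == "outlet":
            continue
        node.role = "endpoint" if len(inc[nid]) <= 1 else "junction"


# ---------------------------------------------------------------------------
# Outlets


def identify_outlets(
    net: ChannelNetwork, mask: ChannelMask, seaward_edge: str = "bottom"
) -> ChannelNetwork:
    """Mark per-component outlet nodes on the seaward edge.

    Endpoints within 2 pixels of the seaward raster edge become outlets; a
    component without such an endpoint gets its endpoint (or, failing that,
    node) closest to the seaward edge.
    """
    if seaward_edge not in ("top", "bottom", "left", "right"):
        raise ValueError(f"unknown seaward edge: {seaward_edge}")
    grid = mask.grid
    nrows, ncols = grid.shape
    ps = net.pixel_size

    def edge_distance_px(node: Node) -> float:
        row, col = grid.world_to_pixel(node.x, node.y)
        if seaward_edge == "bottom":
            return (nrows - 1) - row
        if seaward_edge == "top":
            return row
        if seaward_edge == "left":
            return col
        return (ncols - 1) - col

    comp_nodes: dict[int, set[int]] = {}
    for e in net.edges.values():
        comp_nodes.setdefault(e.component_id, set()).update((e.a, e.b))

    inc = net.incident()
    for cid in sorted(comp_nodes):
        nids = sorted(comp_nodes[cid])
        endpoints = [n for n in nids if len(inc[n]) <= 1]
        candidates = endpoints or nids
        marked = False
        for nid in candidates:
            if edge_distance_px(net.nodes[nid]) <= 2.0:
                net.nodes[nid].role = "outlet"
                marked = True
        if not marked:
            best = min(candidates, key=lambda n: (edge_distance_px(net.nodes[n]), n))
            net.nodes[best].role = "outlet"
    return net


# ---------------------------------------------------------------------------
# Strahler ordering


def assign_strahler(net: ChannelNetwork) -> ChannelNetwork:
    """Assign Strahler orders per component, rooted at its outlet.

    Components containing cycles are first reduced to trees by dropping, for
    every cycle, the edge whose midpoint is graph-farthest from the outlet
    (a warning is logged); dropped edges get the order of a leaf (1).
    """
    if not net.outlets():
        if net.edges:
            raise ValueError("outlets must be identified before ordering")
        return net

    comp_nodes: dict[int, set[int]] = {}
    comp_edges: dict[int, list[int]] = {}
    for eid, e in net.edges.items():
        comp_nodes.setdefault(e.component_id, set()).update((e.a, e.b))
        comp_edges.setdefault(e.component_id, []).append(eid)

    for cid in sorted(comp_edges):
        nids = comp_nodes[cid]
        roots = sorted(n for n in nids if net.nodes[n].role == "outlet")
        if not roots:
            raise ValueError(f"component {cid} has no outlet")
        root = roots[0]
        eids = comp_edges[cid]
        tree_eids = _spanning_tree(net, eids, root)
        dropped = set(eids) - set(tree_eids)
        if dropped:
            logger.warning(
                "component %d contains cycles; %d edge(s) dropped from ordering",
                cid,
                len(dropped),
            )
        _order_tree(net, tree_eids, root)
        for eid in dropped:
            net.edges[eid].strahler_order = 1
    return net


def _dijkstra(net: ChannelNetwork, eids: list[int], root: int) -> dict[int, float]:
    import heapq

    adj: dict[int, list[tuple[int, float]]] = {}
    for eid in eids:
        e = net.edges[eid]
        adj.setdefault(e.a, []).append((e.b, e.length))
        adj.setdefault(e.b, []).append((e.a, e.length))
    dist = {root: 0.0}
    heap = [(0.0, root)]
    while heap:
        d, n = heapq.heappop(heap)
        if d > dist.get(n, math.inf):
            continue
        for m, w in adj.get(n, []):
            nd = d + w
            if nd < dist.get(m, math.inf):
                dist[m] = nd
                heapq.heappush(heap, (nd, m))
    return dist


def _spanning_tree(net: ChannelNetwork, eids: list[int], root: int) -> list[int]:
    """Kruskal-style: keep edges in ascending midpoint distance from root, so
    cycle-closing edges with the farthest midpoints are the ones dropped."""
    dist = _dijkstra(net, eids, root)

    def midpoint_dist(eid):
        e = net.edges[eid]
        return (dist.get(e.a, 0.0) + dist.get(e.b, 0.0) + e.length) / 2.0

    parent: dict[int, int] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept = []
    for eid in sorted(eids, key=lambda i: (midpoint_dist(i), i)):
        e = net.edges[eid]
        ra, rb = find(e.a), find(e.b)
        if ra == rb:
            continue
        parent[ra] = rb
        kept.append(eid)
    return kept


def _order_tree(net: ChannelNetwork, eids: list[int], root: int) -> None:
    adj: dict[int, list[tuple[int, int]]] = {}
    for eid in eids:
        e = net.edges[eid]
        adj.setdefault(e.a, []).append((eid, e.b))
        adj.setdefault(e.b, []).append((eid, e.a))

    # iterative post-order over (edge, child-node) pairs rooted at the outlet
    order_of: dict[int, int] = {}
    stack = [(eid, child, False) for eid, child in adj.get(root, [])]
    while stack:
        eid, node, expanded = stack.pop()
        children = [(ce, cn) for ce, cn in adj.get(node, []) if ce != eid]
        if not expanded:
            stack.append((eid, node, True))
            for ce, cn in children:
                stack.append((ce, cn, False))
        else:
            if not children:
                order_of[eid] = 1
            else:
                sub = [order_of[ce] for ce, _ in children]
                m = max(sub)
                order_of[eid] = m + 1 if sub.count(m) >= 2 else m
    for eid in eids:
        net.edges[eid].strahler_order = order_of.get(eid, 1)


# ---------------------------------------------------------------------------
# Measurements and pruning


def total_length(net: ChannelNetwork) -> float:
    """Sum of all edge lengths in meters (0 for an empty network)."""
    return float(sum(e.length for e in net.edges.values()))


def component_lengths(net: ChannelNetwork) -> dict[int, float]:
    out: dict[int, float] = {}
    for e in net.edges.values():
        out[e.component_id] = out.get(e.component_id, 0.0) + e.length
    return out


def prune_orders(net: ChannelNetwork, removed_max_order: int) -> ChannelNetwork:
    """Remove all edges with Strahler order <= ``removed_max_order``.

    Surviving edges keep their original orders (no recomputation); r = 0 is
    the identity.
    """
    r = int(removed_max_order)
    if r < 0:
        raise ValueError("removed_max_order must be >= 0")
    if r == 0:
        return net.copy()
    if any(e.strahler_order is None for e in net.edges.values()):
        raise ValueError("orders not assigned")
    out = ChannelNetwork(net.pixel_size)
    keep_nodes = set()
    for eid in sorted(net.edges):
        e = net.edges[eid]
        if e.strahler_order > r:
            keep_nodes.update((e.a, e.b))
    remap = {}
    for nid in sorted(keep_nodes):
        n = net.nodes[nid]
        remap[nid] = out.add_node(n.x, n.y, n.role)
    for eid in sorted(net.edges):
        e = net.edges[eid]
        if e.strahler_order > r:
            out.add_edge(
                remap[e.a], remap[e.b], e.points, e.strahler_order, e.component_id
            )
    return out


# ---------------------------------------------------------------------------
# Rasterization (used by synthetic truth and the correction loop)


def rasterize_network(
    net: ChannelNetwork,
    reference: RasterGrid,
    width_px: int | dict[int, int] = 1,
) -> np.ndarray:
    """Burn edge polylines into a boolean raster on the reference grid.

    ``width_px`` is either a single stroke width or a map from Strahler
    order to width (pixels); widths are applied by dilation with a disk of
    radius ``(width - 1) / 2`` rounded up.
    """
    from skimage.morphology import dilation, disk

    shape = reference.shape
    if isinstance(width_px, dict):
        widths = sorted({int(w) for w in width_px.values()})
        layers = {w: np.zeros(shape, dtype=bool) for w in widths}
    else:
        layers = {int(width_px): np.zeros(shape, dtype=bool)}

    for e in net.edges.values():
        if isinstance(width_px, dict):
            w = int(width_px.get(e.strahler_order or 1, 1))
        else:
            w = int(width_px)
        layer = layers[w]
        for (x0, y0), (x1, y1) in zip(e.points, e.points[1:]):
            r0, c0 = reference.world_to_pixel(x0, y0)
            r1, c1 = reference.world_to_pixel(x1, y1)
            rr, cc = draw_line(
                int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1))
            )
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            layer[rr[ok], cc[ok]] = True

    out = np.zeros(shape, dtype=bool)
    for w, layer in layers.items():
        if w > 1 and layer.any():
            layer = dilation(layer, disk(w // 2))
        out |= layer
    return out
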