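"""Contact-network substrates: the Household Network Model and the Red-Blue tree.

The Household Network Model (HNM) partitions ``N`` agents into households of
constant size ``d_h + 1``; every household is a clique, and every agent
additionally carries ``d_c`` external half-edges that are paired uniformly at
random (a configuration model). Pairings that would create a self-loop or a
duplicate edge (including duplicates of a household edge) are discarded, so
the realized external degree of a node is at most ``d_c``.

The Red-Blue (RB) tree is the deterministic two-type branching tree that
locally approximates the HNM around a uniformly chosen node: red nodes are
the first-reachable member of each household, blue nodes the remaining
household members. The root is red with ``d_c`` red and ``d_h`` blue
children; other red nodes have ``d_c - 1`` red and ``d_h`` blue children;
blue nodes have ``d_c`` red children. The tree is materialized lazily so it
can stand in for the infinite object.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

RED = "red"
BLUE = "blue"


@dataclass
class HouseholdNetwork:
    """Static contact graph partitioned into equal-size households."""

    N: int
    d_h: int
    d_c: int
    households: list[tuple[int, ...]]
    graph: nx.Graph
    n_household_edges: int = 0
    n_external_edges: int = 0
    n_discarded_pairings: int = 0
    _household_of: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._household_of:
            for hid, block in enumerate(self.households):
                for v in block:
                    self._household_of[v] = hid

    def _check_node(self, v: int) -> None:
        if v not in self.graph:
            raise ValueError(f"unknown node id {v!r}")

    def household_of(self, v: int) -> set[int]:
        """All members of v's household, v included (a ``d_h + 1`` block)."""
        self._check_node(v)
        return set(self.households[self._household_of[v]])

    def neighbors(self, v: int) -> set[int]:
        self._check_node(v)
        return set(self.graph.neighbors(v))

    def degree(self, v: int) -> int:
        self._check_node(v)
        return self.graph.degree(v)

    def nodes(self) -> list[int]:
        return list(range(self.N))

    @property
    def edges(self) -> set[frozenset[int]]:
        return {frozenset(e) for e in self.graph.edges()}


def generate_hnm(N: int, d_h: int, d_c: int, seed: int) -> HouseholdNetwork:
    """Draw a Household Network Model.

    Nodes ``0..N-1`` are split into consecutive households of size
    ``d_h + 1`` (cliques). The ``N * d_c`` external half-edges are paired by a
    uniform random matching; self-loops and duplicate edges are discarded.

    Raises
    ------
    ValueError
        If ``N`` is not divisible by ``d_h + 1``, ``d_c < 1``, ``d_h < 0``,
        or the half-edge total ``N * d_c`` is odd.
    """
    if d_h < 0:
        raise ValueError("d_h must be >= 0")
    if d_c < 1:
        raise ValueError("d_c must be >= 1 (no external half-edges to pair otherwise)")
    if N % (d_h + 1) != 0:
        raise ValueError(
            f"N={N} is not divisible by the household size d_h+1={d_h + 1}"
        )
    if (N * d_c) % 2 != 0:
        raise ValueError(f"half-edge total N*d_c={N * d_c} must be even")

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(N))

    households = []
    for start in range(0, N, d_h + 1):
        block = tuple(range(start, start + d_h + 1))
        households.append(block)
        for i, u in enumerate(block):
            for v in block[i + 1 :]:
                g.add_edge(u, v, kind="household")
    n_household = g.number_of_edges()

    half_edges = np.repeat(np.arange(N), d_c)
    rng.shuffle(half_edges)
    n_external = 0
    n_discarded = 0
    for i in range(0, len(half_edges), 2):
        u, v = int(half_edges[i]), int(half_edges[i + 1])
        if u == v or g.has_edge(u, v):
            n_discarded += 1
            continue
        g.add_edge(u, v, kind="external")
        n_external += 1

    return HouseholdNetwork(
        N=N,
        d_h=d_h,
        d_c=d_c,
        households=households,
        graph=g,
        n_household_edges=n_household,
        n_external_edges=n_external,
        n_discarded_pairings=n_discarded,
    )


def graph_distance(net: HouseholdNetwork, u: int, v: int) -> Optional[int]:
    """Shortest-path hop count between u and v; ``None`` if disconnected."""
    net._check_node(u)
    net._check_node(v)
    try:
        return nx.shortest_path_length(net.graph, u, v)
    except nx.NetworkXNoPath:
        return None


def household_of(net: HouseholdNetwork, v: int) -> set[int]:
    return net.household_of(v)


# ---------------------------------------------------------------------------
# Red-Blue tree
# ---------------------------------------------------------------------------


@dataclass
class RBNode:
    color: str
    level: int
    parent: Optional[int]
    children: Optional[list[int]] = None  # None = not yet materialized


class RBTree:
    """Lazily materialized Red-Blue tree with branching parameters (d_c, d_h).

    Node ids are assigned in materialization order (the root is 0; breadth
    first when built eagerly). ``ensure_children`` realizes a node's offspring
    on demand, so the tree can serve as a finite window onto the infinite
    object.
    """

    def __init__(self, d_c: int, d_h: int, max_depth: int = 0):
        if d_c < 1 or d_h < 0 or max_depth < 0:
            raise ValueError("require d_c >= 1, d_h >= 0, max_depth >= 0")
        self.d_c = d_c
        self.d_h = d_h
        self.max_depth = max_depth
        self.nodes: dict[int, RBNode] = {0: RBNode(RED, 0, None)}
        self._next_id = 1
        self.root = 0

    def _check_node(self, v: int) -> None:
        if v not in self.nodes:
            raise ValueError(f"unknown node id {v!r}")

    def ensure_children(self, v: int) -> list[int]:
        """Materialize (once) and return v's children, red before blue."""
        self._check_node(v)
        node = self.nodes[v]
        if node.children is not None:
            return node.children
        if node.color == RED:
            n_red = self.d_c if v == self.root else self.d_c - 1
            n_blue = self.d_h
        else:
            n_red, n_blue = self.d_c, 0
        kids = []
        for color, count in ((RED, n_red), (BLUE, n_blue)):
            for _ in range(count):
                cid = self._next_id
                self._next_id += 1
                self.nodes[cid] = RBNode(color, node.level + 1, v)
                kids.append(cid)
        node.children = kids
        self.max_depth = max(self.max_depth, node.level + 1 if kids else node.level)
        return kids

    def children(self, v: int) -> list[int]:
        return self.ensure_children(v)

    def parent(self, v: int) -> Optional[int]:
        self._check_node(v)
        return self.nodes[v].parent

    def color(self, v: int) -> str:
        self._check_node(v)
        return self.nodes[v].color

    def level(self, v: int) -> int:
        self._check_node(v)
        return self.nodes[v].level

    def neighbors(self, v: int) -> set[int]:
        """Tree neighbors: the parent plus all (materialized-on-demand) children."""
        self._check_node(v)
        out = set(self.ensure_children(v))
        p = self.nodes[v].parent
        if p is not None:
            out.add(p)
        return out

    def household_of(self, v: int) -> set[int]:
        """The household block: a red node grouped with its d_h blue children."""
        self._check_node(v)
        head = v if self.nodes[v].color == RED else self.nodes[v].parent
        block = {head}
        block.update(
            c for c in self.ensure_children(head) if self.nodes[c].color == BLUE
        )
        return block

    def realized_level_counts(self) -> dict[int, tuple[int, int]]:
        """(red, blue) counts per fully realized level."""
        counts: dict[int, list[int]] = {}
        for node in self.nodes.values():
            r, b = counts.setdefault(node.level, [0, 0])
            if node.color == RED:
                counts[node.level][0] += 1
            else:
                counts[node.level][1] += 1
        return {l: (rb[0], rb[1]) for l, rb in counts.items()}


def build_rb_tree(d_c: int, d_h: int, max_depth: int) -> RBTree:
    """Materialize an RB tree breadth-first down to ``max_depth``."""
    tree = RBTree(d_c, d_h, max_depth)
    frontier = [tree.root]
    for _ in range(max_depth):
        nxt: list[int] = []
        for v in frontier:
            nxt.extend(tree.ensure_children(v))
        frontier = nxt
    return tree


def rb_level_count(d_c: int, d_h: int, n: int) -> int:
    """Number of RB-tree nodes at level ``n`` (integer-exact recurrence).

    Level populations follow the two-type recurrence
    ``r_{l+1} = (d_c - 1) r_l + d_c b_l``, ``b_{l+1} = d_h r_l`` with the
    root's special offspring (d_c red, d_h blue) seeding level 1.
    """
    if n < 0:
        raise ValueError("level must be >= 0")
    if n == 0:
        return 1
    r, b = d_c, d_h  # level 1: the root's children
    for _ in range(n - 1):
        r, b = (d_c - 1) * r + d_c * b, d_h * r
    return r + b


# ---------------------------------------------------------------------------
# Plain-text interchange
# ---------------------------------------------------------------------------


def write_edge_list(net: HouseholdNetwork, path: str) -> None:
    """Two-column CSV of node-id pairs, one undirected edge per line."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges()):
            w.writerow([u, v])


def write_households(net: HouseholdNetwork, path: str) -> None:
    """CSV of (node_id, household_id)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for hid, block in enumerate(net.households):
            for v in block:
                w.writerow([v, hid])


def read_network(edge_path: str, household_path: str, d_c: int) -> HouseholdNetwork:
    """Rebuild a HouseholdNetwork from its edge-list and membership files."""
    blocks: dict[int, list[int]] = {}
    with open(household_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            v, hid = int(row[0]), int(row[1])
            blocks.setdefault(hid, []).append(v)
    households = [tuple(sorted(blocks[h])) for h in sorted(blocks)]
    sizes = {len(b) for b in households}
    if len(sizes) != 1:
        raise ValueError("household blocks must all have the same size")
    d_h = sizes.pop() - 1
    N = sum(len(b) for b in households)

    g = nx.Graph()
    g.add_nodes_from(range(N))
    member = {v: hid for hid, b in enumerate(households) for v in b}
    n_household = n_external = 0
    with open(edge_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            u, v = int(row[0]), int(row[1])
            kind = "household" if member[u] == member[v] else "external"
            g.add_edge(u, v, kind=kind)
            if kind == "household":
                n_household += 1
            else:
                n_external += 1
    return HouseholdNetwork(
        N=N,
        d_h=d_h,
        d_c=d_c,
        households=households,
        graph=g,
        n_household_edges=n_household,
        n_external_edges=n_external,
    )


def hnm_edge_categories(net: HouseholdNetwork) -> dict[str, int]:
    """Audit helper: recount edges by category directly from the graph."""
    counts = {"household": 0, "external": 0}
    for u, v, data in net.graph.edges(data=True):
        counts[data.get("kind", "external")] += 1
    return counts
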