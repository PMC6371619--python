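"""Rooted ultrametric time trees.

A :class:`TimeTree` is a rooted binary tree over named taxa in which every
node carries a height (time before the present); leaves sit at height 0 and
every parent is strictly older than its children.  Branch lengths in time
units are height differences; the substitution process sees them scaled by
the clock rate and per-branch rate multipliers.

Nodes are integers: leaves ``0..n-1`` (leaf ``i`` is taxon ``taxa[i]``),
internal nodes ``n..2n-2``.  This flat array layout keeps Metropolis
proposals and pruning cheap and makes deep copies trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeTree", "CladeKey", "from_dendropy", "from_linkage"]

#: A clade identity usable across sampled trees: the frozenset of taxon names
#: descending from a node (outgroup excluded by convention of the caller).
CladeKey = frozenset


@dataclass
class TimeTree:
    taxa: list[str]
    parent: np.ndarray  # (2n-1,) int; parent[root] == -1
    children: np.ndarray  # (2n-1, 2) int; -1 rows for leaves
    heights: np.ndarray  # (2n-1,) float; leaves at 0
    rates: np.ndarray | None = None  # per-branch multiplier on node's parent branch
    outgroup: str | None = None
    metadata: dict = field(default_factory=dict)

    # -- construction / validation ------------------------------------------------

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.children = np.asarray(self.children, dtype=np.int64)
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.rates is None:
            self.rates = np.ones(self.n_nodes)
        else:
            self.rates = np.asarray(self.rates, dtype=np.float64)

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def leaf_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.taxa)}

    def validate(self) -> None:
        n = self.n_leaves
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon names")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("non-finite node heights")
        if np.count_nonzero(self.parent == -1) != 1:
            raise ValueError("tree must have exactly one root")
        for node in range(self.n_nodes):
            p = self.parent[node]
            if p >= 0 and not self.heights[p] > self.heights[node]:
                raise ValueError(
                    f"parent {p} (h={self.heights[p]}) not above node "
                    f"{node} (h={self.heights[node]})"
                )
        if not np.all(self.rates[self.parent >= 0] > 0):
            raise ValueError("branch rate multipliers must be positive")

    def copy(self) -> "TimeTree":
        return TimeTree(
            taxa=list(self.taxa),
            parent=self.parent.copy(),
            children=self.children.copy(),
            heights=self.heights.copy(),
            rates=self.rates.copy(),
            outgroup=self.outgroup,
            metadata=dict(self.metadata),
        )

    # -- traversal ----------------------------------------------------------------

    def postorder(self) -> list[int]:
        """Node ids, children always before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            if self.children[node, 0] >= 0:
                stack.extend(self.children[node])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def leaves_under(self, node: int) -> list[int]:
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.children[v, 0] < 0:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def clades(self, include_leaves: bool = False) -> dict[int, CladeKey]:
        """Map node id -> frozenset of ingroup taxon names below it.

        The outgroup taxon (if any) never appears in a clade key, so keys
        are comparable across trees that differ in outgroup placement.  On
        the outgroup stem several nodes share the full-ingroup key; only
        the most recent (lowest) such node — the actual ingroup MRCA — is
        kept, so keys identify nodes uniquely.
        """
        sets: dict[int, frozenset] = {}
        for node in self.postorder():
            if self.children[node, 0] < 0:
                name = self.taxa[node]
                sets[node] = (
                    frozenset() if name == self.outgroup else frozenset([name])
                )
            else:
                l, r = self.children[node]
                sets[node] = sets[l] | sets[r]
        if not include_leaves:
            best: dict = {}
            for v, k in sets.items():
                if self.children[v, 0] < 0 or len(k) == 0:
                    continue
                if k not in best or self.heights[v] < self.heights[best[k]]:
                    best[k] = v
            return {v: k for k, v in best.items()}
        return {v: k for v, k in sets.items() if len(k) > 0}

    def branch_lengths(self) -> np.ndarray:
        """Time-length of the branch above each node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = (
            self.heights[self.parent[has_parent]] - self.heights[has_parent]
        )
        return bl

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    # -- serialization ------------------------------------------------------------

    def newick(
        self,
        annotations: dict[int, str] | None = None,
        fmt: str = "%.8g",
    ) -> str:
        """Newick string with branch lengths in time units.

        ``annotations`` maps node id -> a raw comment string inserted after
        the node (e.g. ``"[&support=0.95]"``).
        """
        ann = annotations or {}

        def rec(node: int) -> str:
            if self.children[node, 0] < 0:
                label = self.taxa[node]
            else:
                l, r = self.children[node]
                label = f"({rec(l)},{rec(r)})"
            label += ann.get(node, "")
            p = self.parent[node]
            if p >= 0:
                label += ":" + fmt % (self.heights[p] - self.heights[node])
            return label

        return rec(self.root) + ";"

    def topology_key(self) -> frozenset:
        """Order-free identity of the labelled rooted topology."""
        return frozenset(self.clades().values())


# -- converters -------------------------------------------------------------------


def from_linkage(Z: np.ndarray, taxa: list[str]) -> TimeTree:
    """Build a TimeTree from a scipy hierarchical-clustering linkage matrix.

    Linkage merge heights are interpreted as pairwise distances; node heights
    are half of those (ultrametric divergence time).  Heights are nudged up
    where ties would violate strict parent>child ordering.
    """
    n = len(taxa)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    heights = np.zeros(2 * n - 1)
    for k in range(n - 1):
        a, b, dist, _ = Z[k]
        node = n + k
        a, b = int(a), int(b)
        parent[a] = parent[b] = node
        children[node] = (a, b)
        h = dist / 2.0
        floor = max(heights[a], heights[b])
        eps = 1e-6 * (1.0 + floor)
        heights[node] = max(h, floor + eps)
    tree = TimeTree(taxa=list(taxa), parent=parent, children=children, heights=heights)
    tree.validate()
    return tree


def from_dendropy(dtree, outgroup: str | None = None) -> TimeTree:
    """Convert a rooted dendropy tree with branch lengths to a TimeTree.

    Node heights are set as (max root-to-leaf path) - (root-to-node path);
    small deviations from ultrametricity are tolerated by flooring each
    parent strictly above its children.
    """
    leaves = [lf for lf in dtree.leaf_node_iter()]
    taxa = [lf.taxon.label for lf in leaves]
    n = len(taxa)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    depth: dict = {}
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    max_depth = max(depth[lf] for lf in leaves)
    ids: dict = {lf: i for i, lf in enumerate(leaves)}
    nxt = n
    for nd in dtree.postorder_internal_node_iter():
        ids[nd] = nxt
        nxt += 1
    if nxt != 2 * n - 1:
        raise ValueError("tree is not strictly binary")
    heights = np.zeros(2 * n - 1)
    for nd, i in ids.items():
        heights[i] = max_depth - depth[nd]
    for nd in dtree.postorder_internal_node_iter():
        ch = nd.child_nodes()
        if len(ch) != 2:
            raise ValueError("tree is not strictly binary")
        i = ids[nd]
        children[i] = (ids[ch[0]], ids[ch[1]])
        parent[ids[ch[0]]] = parent[ids[ch[1]]] = i
        floor = max(heights[ids[ch[0]]], heights[ids[ch[1]]])
        if heights[i] <= floor:
            heights[i] = floor + 1e-9 * (1.0 + floor)
    tree = TimeTree(
        taxa=taxa, parent=parent, children=children, heights=heights, outgroup=outgroup
    )
    tree.validate()
    return tree
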