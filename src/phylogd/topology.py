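"""Clone-tree topologies for tumour-evolution simulation.

A tumour phylogeny is a rooted tree whose nodes are clones.  Node 0 is the
germline diploid ancestor; its single child is the most recent common
ancestor (MRCA) of all sequenced tumour cells.  The edge germline -> MRCA
is the trunk, and mutations assigned to it are truncal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GERMLINE = 0

#: clone-count ranges by sample-size group (low: 2-3 samples, medium: 4-7,
#: high: >7), matching ranges observed in large multi-region NSCLC cohorts.
CLONE_RANGES = {"low": (8, 16), "medium": (12, 24), "high": (22, 30)}
SAMPLE_RANGES = {"low": (2, 3), "medium": (4, 7), "high": (8, 10)}


@dataclass
class PhylogenyTopology:
    """Germline-rooted clone tree.

    ``parent_of`` maps every non-germline clone to its parent; tumour
    clones are numbered 1..n_clones with clone 1 the MRCA.
    """

    parent_of: dict[int, int]
    germline_root: int = GERMLINE
    mrca: int = 1
    _children: dict[int, list[int]] = field(default=None, repr=False)

    def __post_init__(self):
        kids: dict[int, list[int]] = {self.germline_root: []}
        for c, p in sorted(self.parent_of.items()):
            kids.setdefault(p, [])
            kids.setdefault(c, [])
            kids[p].append(c)
        self._children = kids
        if self.children(self.germline_root) != [self.mrca]:
            raise ValueError("germline root must have exactly one child (the MRCA)")

    @property
    def nodes(self) -> list[int]:
        return [self.germline_root] + sorted(self.parent_of)

    @property
    def clones(self) -> list[int]:
        """Tumour clones (everything except the germline root)."""
        return sorted(self.parent_of)

    @property
    def n_clones(self) -> int:
        return len(self.parent_of)

    def children(self, node: int) -> list[int]:
        return list(self._children.get(node, []))

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs; the first returned edge is the trunk."""
        return [(self.parent_of[c], c) for c in sorted(self.parent_of)]

    def subclonal_edges(self) -> list[tuple[int, int]]:
        return [(p, c) for p, c in self.edges() if c != self.mrca]

    def subtree(self, node: int) -> set[int]:
        """All clones at or below ``node``."""
        out, stack = set(), [node]
        while stack:
            v = stack.pop()
            out.add(v)
            stack.extend(self._children.get(v, []))
        return out

    def ancestors(self, node: int) -> list[int]:
        """Path of ancestors from ``node`` (exclusive) up to the germline root."""
        out = []
        while node != self.germline_root:
            node = self.parent_of[node]
            out.append(node)
        return out

    def validate(self) -> None:
        nodes = set(self.nodes)
        if self.germline_root in self.parent_of:
            raise ValueError("germline root cannot have a parent")
        for c, p in self.parent_of.items():
            if p not in nodes:
                raise ValueError(f"parent {p} of {c} not a node")
        # reachability from the root proves connectedness and acyclicity
        if self.subtree(self.germline_root) != nodes:
            raise ValueError("tree is not connected/acyclic")


def draw_n_clones(sample_group: str, rng: np.random.Generator) -> int:
    """Draw a clone count uniformly from the range of the sample-size group."""
    lo, hi = CLONE_RANGES[sample_group]
    return int(rng.integers(lo, hi + 1))


def simulate_topology(n_clones: int, rng: np.random.Generator) -> PhylogenyTopology:
    """Simulate a random clone-tree topology with ``n_clones`` tumour clones.

    A full rooted binary tree with ``n_clones`` leaves is generated first and
    random leaves are then removed iteratively until ``n_clones`` nodes
    remain (every n-node tree can be refined into a full binary tree, so
    every topology is reachable).  A germline root is finally attached above
    the surviving root, which represents the MRCA.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    # full binary tree with n_clones leaves via recursive random splits
    parent: dict[int, int] = {}
    next_id = [1]

    def grow(node: int, n_leaves: int) -> None:
        if n_leaves == 1:
            return
        k = int(rng.integers(1, n_leaves))  # leaves in the left subtree
        for n_sub in (k, n_leaves - k):
            child = next_id[0]
            next_id[0] += 1
            parent[child] = node
            grow(child, n_sub)

    root = 0
    grow(root, n_clones)
    nodes = {root} | set(parent)
    while len(nodes) > n_clones:
        leaves = sorted(v for v in nodes if not any(p == v for p in parent.values()))
        drop = leaves[int(rng.integers(len(leaves)))]
        nodes.discard(drop)
        parent.pop(drop, None)

    # relabel: MRCA (= surviving root) -> 1, the rest 2..n in BFS order
    relabel = {root: 1}
    order = [root]
    while order:
        v = order.pop(0)
        for c in sorted(u for u, p in parent.items() if p == v and u in nodes):
            relabel[c] = len(relabel) + 1
            order.append(c)
    parent_of = {relabel[c]: relabel[p] for c, p in parent.items() if c in nodes}
    parent_of[1] = GERMLINE
    topo = PhylogenyTopology(parent_of)
    topo.validate()
    return topo
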