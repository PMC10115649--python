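"""Clone-tree reconstruction from cluster PhyloCCF vectors.

Trees are parent maps over cluster ids rooted at the trunk cluster.  Two
rules constrain nesting, each with an absolute PhyloCCF tolerance:

* pigeonhole principle: in every region, a parent's PhyloCCF must be at
  least the sum of its children's PhyloCCFs (minus the tolerance);
* crossing rule: a cluster may be ancestral to another only if its
  PhyloCCF is at least the descendant's (minus the tolerance) in every
  region.

``enumerate_trees`` returns every parent map satisfying both rules (up to
a cap); the default tree maximises the summed parent-child concordance
sum over edges of min over regions of (CCF(parent) - CCF(child)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

TOLERANCE = 0.1
ENUM_CAP = 1000


@dataclass
class CloneTree:
    parent_of: dict[int, int]  # cluster -> parent cluster; trunk absent
    trunk: int
    is_default: bool = True
    alternatives: list[dict[int, int]] = field(default_factory=list)
    truncated: bool = False

    def nodes(self) -> list[int]:
        return sorted({self.trunk, *self.parent_of})

    def children(self, node: int) -> list[int]:
        return sorted(c for c, p in self.parent_of.items() if p == node)

    def leaves(self) -> list[int]:
        parents = set(self.parent_of.values())
        return sorted(n for n in self.nodes() if n not in parents)


def validate_tree(
    parent_of: dict[int, int],
    ccf: dict[int, np.ndarray],
    trunk: int,
    tol: float = TOLERANCE,
) -> bool:
    """Independent direct check of the pigeonhole and crossing rules."""
    nodes = {trunk, *parent_of}
    if set(parent_of) != nodes - {trunk}:
        return False
    # connectivity / acyclicity: every node reaches the trunk
    for n in parent_of:
        seen, v = set(), n
        while v != trunk:
            if v in seen or v not in parent_of:
                return False
            seen.add(v)
            v = parent_of[v]
    # crossing rule over all ancestor-descendant pairs
    for n in parent_of:
        v = n
        while v != trunk:
            v = parent_of[v]
            if np.any(np.nan_to_num(ccf[v]) < np.nan_to_num(ccf[n]) - tol):
                return False
    # pigeonhole per parent
    for p in nodes:
        kids = [c for c, q in parent_of.items() if q == p]
        if kids:
            total = np.sum([np.nan_to_num(ccf[c]) for c in kids], axis=0)
            if np.any(total > np.nan_to_num(ccf[p]) + tol):
                return False
    return True


def brute_force_enumerate(
    ccf: dict[int, np.ndarray],
    trunk: int,
    tol: float = TOLERANCE,
) -> list[dict[int, int]]:
    """Exhaustive oracle: test every possible parent map (small inputs)."""
    others = sorted(set(ccf) - {trunk})
    out = []
    for parents in itertools.product(sorted(ccf), repeat=len(others)):
        pm = dict(zip(others, parents))
        if any(c == p for c, p in pm.items()):
            continue
        if validate_tree(pm, ccf, trunk, tol):
            out.append(pm)
    return out


def enumerate_trees(
    ccf: dict[int, np.ndarray],
    trunk: int,
    tol: float = TOLERANCE,
    cap: int = ENUM_CAP,
) -> tuple[list[dict[int, int]], bool]:
    """All rule-satisfying parent maps via pruned recursive insertion.

    Clusters are inserted in decreasing total-PhyloCCF order; each tries
    every already-placed node as a parent, pruning on the crossing rule
    against all ancestors and on the pigeonhole slack of the parent.
    Returns (parent maps, truncated flag).
    """
    clean = {k: np.nan_to_num(np.asarray(v, dtype=float)) for k, v in ccf.items()}
    order = sorted(set(clean) - {trunk}, key=lambda k: (-clean[k].sum(), k))
    results: list[dict[int, int]] = []
    truncated = [False]

    def recurse(i: int, parent_of: dict[int, int], child_sum: dict[int, np.ndarray]):
        if truncated[0]:
            return
        if i == len(order):
            results.append(dict(parent_of))
            if len(results) >= cap:
                truncated[0] = True
            return
        node = order[i]
        for cand in [trunk] + order[:i]:
            # crossing rule against cand and all its ancestors
            v, ok = cand, True
            while True:
                if np.any(clean[v] < clean[node] - tol):
                    ok = False
                    break
                if v == trunk:
                    break
                v = parent_of[v]
            if not ok:
                continue
            new_sum = child_sum.get(cand, 0) + clean[node]
            if np.any(new_sum > clean[cand] + tol):
                continue
            parent_of[node] = cand
            old = child_sum.get(cand)
            child_sum[cand] = new_sum
            recurse(i + 1, parent_of, child_sum)
            del parent_of[node]
            if old is None:
                del child_sum[cand]
            else:
                child_sum[cand] = old
        return

    recurse(0, {}, {})
    return results, truncated[0]


def _concordance(parent_of: dict[int, int], ccf: dict[int, np.ndarray]) -> float:
    return float(
        sum(np.min(np.nan_to_num(ccf[p]) - np.nan_to_num(ccf[c])) for c, p in parent_of.items())
    )


def select_default(trees: list[dict[int, int]], ccf: dict[int, np.ndarray]) -> dict[int, int]:
    """Deterministic default: max concordance, then lexicographic parents."""
    keyed = sorted(
        trees,
        key=lambda pm: (-_concordance(pm, ccf), sorted(pm.items())),
    )
    return keyed[0]


def build_clone_tree(
    ccf: dict[int, np.ndarray],
    trunk: int,
    tol: float = TOLERANCE,
    cap: int = ENUM_CAP,
) -> CloneTree | None:
    """Default tree plus alternatives, or None if no tree satisfies the rules."""
    trees, truncated = enumerate_trees(ccf, trunk, tol, cap)
    if not trees:
        return None
    default = select_default(trees, ccf)
    alts = [t for t in trees if t != default]
    return CloneTree(parent_of=default, trunk=trunk, alternatives=alts, truncated=truncated)


def remove_for_feasibility(
    ccf: dict[int, np.ndarray],
    sizes: dict[int, int],
    trunk: int,
    tol: float = TOLERANCE,
    exhaustive_limit: int = 12,
) -> list[int]:
    """Minimal-mutation cluster removal restoring tree feasibility.

    Searches subsets of removable clusters in increasing total removed
    mutation count (exhaustively up to ``exhaustive_limit`` clusters,
    greedily beyond) until some tree satisfies both rules.  The trunk is
    never removable; raises if no removal subset works.
    """
    removable = sorted(set(ccf) - {trunk})
    if len(removable) <= exhaustive_limit:
        subsets = sorted(
            (s for r in range(len(removable) + 1) for s in itertools.combinations(removable, r)),
            key=lambda s: (sum(sizes[c] for c in s), len(s), s),
        )
        for s in subsets:
            kept = {k: v for k, v in ccf.items() if k not in s}
            trees, _ = enumerate_trees(kept, trunk, tol, cap=1)
            if trees:
                return list(s)
        raise RuntimeError("no cluster subset restores feasibility")
    removed: list[int] = []
    pool = sorted(removable, key=lambda c: (sizes[c], c))
    while pool:
        kept = {k: v for k, v in ccf.items() if k not in removed}
        trees, _ = enumerate_trees(kept, trunk, tol, cap=1)
        if trees:
            return removed
        removed.append(pool.pop(0))
    raise RuntimeError("no cluster subset restores feasibility")


def to_newick(tree: CloneTree, labels: dict[int, str] | None = None) -> str:
    """Newick string with clusters as labelled internal nodes."""
    labels = labels or {}

    def name(n: int) -> str:
        return labels.get(n, f"C{n}")

    def rec(n: int) -> str:
        kids = tree.children(n)
        if not kids:
            return name(n)
        return "(" + ",".join(rec(k) for k in kids) + ")" + name(n)

    return rec(tree.trunk) + ";"
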