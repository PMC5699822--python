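"""Topological tree-to-tree distances: Robinson-Foulds, path distance,
and subtree-prune-regraft (exact breadth-first oracle for small trees,
kernelize-then-greedy-leaf-deletion approximation in general).

All metrics operate on unrooted topologies; branch lengths are ignored.
Multifurcations are allowed for RF and path distance; the SPR machinery
requires binary trees.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .treeqc import read_tree

logger = logging.getLogger(__name__)


class UnrootedTree:
    """Unrooted tree as an adjacency map.

    Leaves are their (string) labels; internal nodes are fresh integers.
    Degree-2 nodes (e.g. a rooted newick's root) are suppressed on
    construction, so path lengths and splits follow the unrooted shape.
    """

    def __init__(self, adj: dict, counter: itertools.count | None = None):
        self.adj = adj
        self._counter = counter or itertools.count(10**6)

    # -- construction -------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "UnrootedTree":
        counter = itertools.count()
        adj: dict = {}
        names: dict[int, object] = {}

        def name_of(node):
            if id(node) not in names:
                if node.is_leaf():
                    names[id(node)] = node.taxon.label if node.taxon else node.label
                else:
                    names[id(node)] = next(counter)
            return names[id(node)]

        for node in tree.preorder_node_iter():
            u = name_of(node)
            adj.setdefault(u, set())
            for child in node.child_nodes():
                v = name_of(child)
                adj[u].add(v)
                adj.setdefault(v, set()).add(u)
        out = cls(adj, counter)
        out._suppress_degree_two()
        return out

    @classmethod
    def from_newick(cls, newick: str) -> "UnrootedTree":
        return cls.from_dendropy(read_tree(newick))

    def copy(self) -> "UnrootedTree":
        return UnrootedTree({k: set(v) for k, v in self.adj.items()}, self._counter)

    # -- basic structure ----------------------------------------------
    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(n for n, nb in self.adj.items() if len(nb) == 1)

    def is_binary(self) -> bool:
        return all(len(nb) in (1, 3) for nb in self.adj.values())

    def edges(self) -> list[tuple[object, object]]:
        seen, out = set(), []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if (v, u) not in seen:
                    seen.add((u, v))
                    out.append((u, v))
        return out

    def _suppress_degree_two(self) -> None:
        while nodes := [
            n for n, nb in self.adj.items() if len(nb) == 2 and not isinstance(n, str)
        ]:
            self._suppress_one(nodes[0])

    def _suppress_one(self, node) -> None:
        a, b = self.adj[node]
        self.adj[a].discard(node)
        self.adj[b].discard(node)
        self.adj[a].add(b)
        self.adj[b].add(a)
        del self.adj[node]

    def delete_leaf(self, leaf: str) -> None:
        (nbr,) = self.adj[leaf]
        self.adj[nbr].discard(leaf)
        del self.adj[leaf]
        if len(self.adj[nbr]) == 2 and not isinstance(nbr, str):
            self._suppress_one(nbr)

    # -- topology invariants -------------------------------------------
    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, canonical side excludes the
        lexicographically first leaf."""
        leaves = self.leaves
        if len(leaves) < 4:
            return frozenset()
        anchor = min(leaves)
        out = set()
        for u, v in self.edges():
            side = self._leaves_beyond(v, u)
            if anchor in side:
                side = leaves - side
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return frozenset(out)

    def _leaves_beyond(self, start, blocked) -> frozenset[str]:
        """Leaves in the component containing ``start`` after cutting the
        edge (blocked, start)."""
        stack, seen, found = [start], {blocked, start}, []
        while stack:
            node = stack.pop()
            if len(self.adj[node]) == 1:
                found.append(node)
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(found)

    def to_newick(self, branch_length: float = 1.0) -> str:
        """Newick string rooted at the neighbor of the first leaf
        (topology only; every edge gets ``branch_length``)."""
        anchor = min(self.leaves)
        (root,) = self.adj[anchor]

        def render(node, parent) -> str:
            if isinstance(node, str):
                return f"{node}:{branch_length}"
            inner = ",".join(
                render(nb, node) for nb in sorted(self.adj[node], key=str)
                if nb != parent
            )
            return f"({inner}):{branch_length}"

        inner = ",".join(
            render(nb, root) for nb in sorted(self.adj[root], key=str)
        )
        return f"({inner});"

    def key(self) -> tuple:
        """Canonical topology key (leaf set + split set)."""
        return (self.leaves, self.splits())

    def leaf_pair_path_lengths(self, order: Sequence[str]) -> np.ndarray:
        """Vector of topological path lengths for all unordered leaf
        pairs, pairs ordered by ``itertools.combinations(order, 2)``."""
        dists = {}
        for leaf in order:
            # BFS edge counts from this leaf
            depth = {leaf: 0}
            queue = deque([leaf])
            while queue:
                node = queue.popleft()
                for nb in self.adj[node]:
                    if nb not in depth:
                        depth[nb] = depth[node] + 1
                        queue.append(nb)
            dists[leaf] = depth
        return np.array(
            [dists[a][b] for a, b in itertools.combinations(order, 2)], dtype=float
        )


def _as_utree(tree) -> UnrootedTree:
    if isinstance(tree, UnrootedTree):
        return tree.copy()
    if isinstance(tree, str):
        return UnrootedTree.from_newick(tree)
    return UnrootedTree.from_dendropy(tree)


def _common_leaves(u1: UnrootedTree, u2: UnrootedTree, restrict_to_shared: bool):
    l1, l2 = u1.leaves, u2.leaves
    if l1 == l2:
        return u1, u2
    shared = l1 & l2
    if not shared:
        raise ValueError("trees share no leaves")
    if not restrict_to_shared:
        raise ValueError(
            f"leaf sets differ ({sorted(l1 ^ l2)}); pass restrict_to_shared=True"
        )
    logger.warning("restricting comparison to %d shared leaves", len(shared))
    for utree, extra in ((u1, l1 - shared), (u2, l2 - shared)):
        for leaf in sorted(extra):
            utree.delete_leaf(leaf)
    return u1, u2


def rf_distance(t1, t2, restrict_to_shared: bool = False) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets (always even for binary
    trees with equal leaf sets)."""
    u1, u2 = _common_leaves(_as_utree(t1), _as_utree(t2), restrict_to_shared)
    return len(u1.splits() ^ u2.splits())


def path_distance(t1, t2) -> float:
    """Euclidean norm of the difference between the trees' vectors of
    leaf-pair topological path lengths (edge counts)."""
    u1, u2 = _as_utree(t1), _as_utree(t2)
    if u1.leaves != u2.leaves:
        raise ValueError("path distance requires identical leaf sets")
    order = sorted(u1.leaves)
    return float(
        np.linalg.norm(u1.leaf_pair_path_lengths(order) - u2.leaf_pair_path_lengths(order))
    )


# ---------------------------------------------------------------------------
# SPR

def spr_neighbors(utree: UnrootedTree) -> list[UnrootedTree]:
    """All topologies one subtree-prune-and-regraft move away.

    For every directed edge (u, v) with u internal, the subtree on v's
    side is pruned (u suppressed) and reattached by subdividing each edge
    of the remaining component.
    """
    if not utree.is_binary():
        raise ValueError("SPR moves require a binary tree")
    out = []
    for u, v in itertools.chain(
        utree.edges(), [(b, a) for a, b in utree.edges()]
    ):
        if isinstance(u, str) or len(utree.adj[u]) != 3:
            continue
        base = utree.copy()
        base.adj[u].discard(v)
        base.adj[v].discard(u)
        a, b = base.adj[u]
        base.adj[a].discard(u)
        base.adj[b].discard(u)
        base.adj[a].add(b)
        base.adj[b].add(a)
        del base.adj[u]
        # remaining component = the one containing a
        remaining = set()
        stack = [a]
        while stack:
            node = stack.pop()
            if node in remaining:
                continue
            remaining.add(node)
            stack.extend(base.adj[node])
        for x, y in base.edges():
            if x not in remaining or y not in remaining:
                continue
            moved = base.copy()
            w = next(moved._counter)
            moved.adj[x].discard(y)
            moved.adj[y].discard(x)
            moved.adj[w] = {x, y, v}
            moved.adj[x].add(w)
            moved.adj[y].add(w)
            moved.adj[v].add(w)
            out.append(moved)
    return out


def spr_distance_exact(t1, t2, max_d: int = 4) -> int | None:
    """Minimal number of SPR moves from t1 to t2 by breadth-first search
    over SPR neighborhoods (oracle; <= 10 leaves).  Returns None when the
    distance exceeds ``max_d``."""
    u1, u2 = _as_utree(t1), _as_utree(t2)
    if u1.leaves != u2.leaves:
        raise ValueError("SPR distance requires identical leaf sets")
    if len(u1.leaves) > 10:
        raise ValueError("exact SPR search limited to <= 10 leaves")
    target = u2.key()
    if u1.key() == target:
        return 0
    frontier = [u1]
    visited = {u1.key()}
    for depth in range(1, max_d + 1):
        next_frontier = []
        for utree in frontier:
            for nb in spr_neighbors(utree):
                k = nb.key()
                if k == target:
                    return depth
                if k not in visited:
                    visited.add(k)
                    next_frontier.append(nb)
        frontier = next_frontier
    return None


def spr_distance_approx(t1, t2) -> int:
    """Upper-bound SPR distance: collapse shared pendant subtrees, then
    greedily delete the leaf whose removal most reduces the RF distance,
    one SPR move per deletion, until the restricted topologies agree.

    Each deleted leaf could be re-inserted at its correct position with a
    single SPR move, so the count is always >= the exact distance, and it
    is 0 exactly when the topologies are identical.
    """
    u1, u2 = _as_utree(t1), _as_utree(t2)
    if u1.leaves != u2.leaves:
        raise ValueError("SPR distance requires identical leaf sets")
    _kernelize(u1, u2)
    moves = 0
    while u1.splits() != u2.splits():
        best = None
        for leaf in sorted(u1.leaves):
            r1, r2 = u1.copy(), u2.copy()
            r1.delete_leaf(leaf)
            r2.delete_leaf(leaf)
            rf = len(r1.splits() ^ r2.splits())
            if best is None or rf < best[0]:
                best = (rf, leaf, r1, r2)
        _, _, u1, u2 = best
        moves += 1
    return moves


def _pendant_cherries(utree: UnrootedTree) -> dict[frozenset[str], str]:
    """Cherries (leaf pairs on one internal node) keyed by the pair."""
    out = {}
    for node, nbrs in utree.adj.items():
        if isinstance(node, str):
            continue
        leaf_nbrs = sorted(n for n in nbrs if isinstance(n, str))
        if len(leaf_nbrs) == 2:
            out[frozenset(leaf_nbrs)] = leaf_nbrs[0]
    return out


def _kernelize(u1: UnrootedTree, u2: UnrootedTree) -> None:
    """Iteratively collapse cherries present in both trees to a single
    leaf (the lexicographically first of the pair), shrinking identical
    pendant subtrees shared by both trees."""
    while len(u1.leaves) > 4:
        shared = set(_pendant_cherries(u1)) & set(_pendant_cherries(u2))
        if not shared:
            return
        pair = sorted(shared, key=sorted)[0]
        drop = sorted(pair)[1]
        u1.delete_leaf(drop)
        u2.delete_leaf(drop)


def pairwise_distance_table(
    trees: Mapping[str, object], restrict_to_shared: bool = False
) -> dict[str, pd.DataFrame]:
    """Lower-triangle matrices of all three metrics for a named tree set.

    The diagonal is '-', the upper triangle empty, matching the layout of
    published tree-comparison tables.
    """
    names = list(trees)
    if len(names) < 2:
        raise ValueError("need >= 2 trees")
    metrics = {
        "rf": lambda a, b: rf_distance(a, b, restrict_to_shared),
        "path": path_distance,
        "spr": spr_distance_approx,
    }
    out = {}
    for metric, fn in metrics.items():
        table = pd.DataFrame("", index=names, columns=names, dtype=object)
        for i, ni in enumerate(names):
            table.loc[ni, ni] = "-"
            for j in range(i):
                value = fn(trees[ni], trees[names[j]])
                table.loc[ni, names[j]] = (
                    f"{value:.1f}" if isinstance(value, float) else str(value)
                )
        out[metric] = table
    return out


def write_distance_tables(
    tables: Mapping[str, pd.DataFrame], out_path: str | Path
) -> None:
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        for metric in sorted(tables):
            fh.write(f"# {metric}\n")
            tables[metric].to_csv(fh, sep="\t")
            fh.write("\n")
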