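"""Independent unrooted-tree oracle used by the NJ consistency tests.

Enumerates every unrooted binary topology on a taxon set by sequential
leaf insertion, assigns distinct rational branch lengths, and computes
exact path distances — all without touching the package's tree code.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


class SimpleUnrootedTree:
    """Adjacency-map tree: leaves are taxon strings, internals are ints."""

    def __init__(self, taxa3):
        a, b, c = taxa3
        self._next = 0
        hub = self._new_internal()
        self.adj = {
            hub: {a: None, b: None, c: None},
            a: {hub: None},
            b: {hub: None},
            c: {hub: None},
        }

    def _new_internal(self):
        self._next += 1
        return self._next

    def copy(self):
        import copy

        out = object.__new__(SimpleUnrootedTree)
        out._next = self._next
        out.adj = {u: dict(nbrs) for u, nbrs in self.adj.items()}
        return out

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                key = frozenset({u, v})
                if key not in seen:
                    seen.add(key)
                    yield (u, v)

    def insert_leaf(self, leaf, edge):
        u, v = edge
        w = self._new_internal()
        del self.adj[u][v]
        del self.adj[v][u]
        self.adj[u][w] = None
        self.adj[v][w] = None
        self.adj[w] = {u: None, v: None, leaf: None}
        self.adj[leaf] = {w: None}

    def leaves(self):
        return sorted(u for u in self.adj if isinstance(u, str))

    def assign_lengths(self):
        for i, (u, v) in enumerate(sorted(self.edges(), key=str)):
            length = Fraction(3 + 2 * i, 40)  # distinct positive rationals
            self.adj[u][v] = length
            self.adj[v][u] = length

    def splits(self):
        """Non-trivial bipartitions, sides normalized away from min taxon."""
        tips = frozenset(self.leaves())
        ref = min(tips)
        out = set()
        for u, v in self.edges():
            side = frozenset(self._leaves_beyond(v, u))
            if ref in side:
                side = tips - side
            if 2 <= len(side) <= len(tips) - 2:
                out.add(side)
        return out

    def _leaves_beyond(self, start, blocked):
        stack = [(start, blocked)]
        found = []
        while stack:
            node, came = stack.pop()
            if isinstance(node, str):
                found.append(node)
            for nbr in self.adj[node]:
                if nbr != came:
                    stack.append((nbr, node))
        return found

    def path_length(self, a, b):
        stack = [(a, None, Fraction(0))]
        while stack:
            node, came, dist = stack.pop()
            if node == b:
                return dist
            for nbr, length in self.adj[node].items():
                if nbr != came:
                    stack.append((nbr, node, dist + length))
        raise KeyError((a, b))


def enumerate_unrooted_trees(taxa):
    """Yield every unrooted binary topology on ``taxa`` (|taxa| >= 3)."""
    assert len(taxa) >= 3
    base = SimpleUnrootedTree(taxa[:3])
    stack = [(base, 3)]
    while stack:
        tree, k = stack.pop()
        if k == len(taxa):
            tree.assign_lengths()
            yield tree
            continue
        for edge in list(tree.edges()):
            bigger = tree.copy()
            bigger.insert_leaf(taxa[k], edge)
            stack.append((bigger, k + 1))


def path_distance_matrix(tree):
    ids = tree.leaves()
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = float(tree.path_length(ids[i], ids[j]))
    return ids, out
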