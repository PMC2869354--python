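"""Neighbor-joining trees, bootstrap support, collapsing and rooting.

Trees are :class:`dendropy.Tree` objects.  Bootstrap support is stored on
internal nodes both as a ``support`` attribute (fraction in [0, 1]) and as
the node label, so it survives Newick round-trips.  Rooting moves nodes
around, so supports are attached to the child node of each internal edge of
the tree they were computed on; after rerooting, the support of the (new)
root edge is no longer meaningful and is ignored downstream.
"""

from __future__ import annotations

import io
import re
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .alignment import AlignedSequenceSet, PairwiseDistanceMatrix, distance_matrix
from .errors import TreeError

__all__ = [
    "neighbor_joining",
    "bootstrap_support",
    "collapse_low_support",
    "root_tree",
    "node_support",
    "read_newick_with_support",
    "write_newick_with_support",
    "two_tip_tree",
]

_SUPPORT_COMMENT = re.compile(r"(?:&?support\s*=\s*)?([0-9]*\.?[0-9]+)")


def node_support(node: dendropy.Node) -> float | None:
    """Bootstrap support of an internal node, if any.

    Reads the ``support`` attribute when present, falling back to parsing
    the node label.  Values above 1 are interpreted as percentages.
    """
    val = getattr(node, "support", None)
    if val is None and node.label:
        try:
            val = float(node.label)
        except ValueError:
            return None
    if val is None:
        return None
    return val / 100.0 if val > 1.0 else float(val)


def _set_support(node: dendropy.Node, value: float) -> None:
    node.support = float(value)
    node.label = f"{value:.6g}"


def _active_matrix(matrix: PairwiseDistanceMatrix, use: str) -> np.ndarray:
    if use == "D":
        return matrix.D.astype(float).copy()
    if use == "K":
        return matrix.K.astype(float).copy()
    raise ValueError(f"use must be 'D' or 'K', got {use!r}")


def neighbor_joining(
    matrix: PairwiseDistanceMatrix, use: str = "D"
) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Deterministic: exact ties in the Q criterion join the pair that comes
    first in row-major order of the current active-node list.  Negative
    branch lengths are clamped to zero.
    """
    n = matrix.n
    if n < 3:
        raise TreeError(f"neighbor joining needs at least 3 tips, got {n}")
    tns = dendropy.TaxonNamespace(list(matrix.ids))
    nodes: list[dendropy.Node] = []
    for rid in matrix.ids:
        leaf = dendropy.Node(taxon=tns.get_taxon(rid))
        nodes.append(leaf)
    dm = _active_matrix(matrix, use)

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major => lexicographically first pair
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = dm[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (dm[i, :] + dm[j, :] - dij)
        dnew[i] = 0.0
        dm[i, :] = dnew
        dm[:, i] = dnew
        keep = [k for k in range(m) if k != j]
        dm = dm[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    # join the last three nodes at an (unrooted) trifurcating seed
    a, b, c = nodes
    dab, dac, dbc = dm[0, 1], dm[0, 2], dm[1, 2]
    seed = dendropy.Node()
    for node, length in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        seed.add_child(node)
        node.edge.length = max(float(length), 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    out: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset({node.taxon.label})
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= out[ch]
            out[node] = frozenset(acc)
    return out


def _splits(tree: dendropy.Tree, all_tips: frozenset[str]) -> dict[frozenset[str], dendropy.Node]:
    """Non-trivial bipartitions, each normalized to the side excluding the
    lexicographically first tip id (so orientation is rooting-independent)."""
    ref = min(all_tips)
    leafsets = _leafsets(tree)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node, ls in leafsets.items():
        if node.parent_node is None or node.is_leaf():
            continue
        side = all_tips - ls if ref in ls else ls
        if 2 <= len(side) <= len(all_tips) - 2:
            out[side] = node
    return out


def bootstrap_support(
    aln: AlignedSequenceSet,
    replicates: int = 1000,
    model: str = "none",
    seed: int | None = None,
    use: str = "D",
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports attached.

    Each replicate resamples the alignment's sites with replacement,
    rebuilds the NJ tree, and every internal edge of the full-data tree is
    assigned the fraction of replicate trees containing its bipartition.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    full_matrix = distance_matrix(aln, model=model)
    tree = neighbor_joining(full_matrix, use=use)
    all_tips = frozenset(aln.ids)
    target = _splits(tree, all_tips)
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    L = aln.length
    for _ in range(replicates):
        idx = rng.integers(0, L, size=L)
        rep_aln = aln.resample_sites(idx)
        rep_matrix = distance_matrix(rep_aln, model=model)
        rep_tree = neighbor_joining(rep_matrix, use=use)
        for split in _splits(rep_tree, all_tips):
            if split in counts:
                counts[split] += 1
    for split, node in target.items():
        _set_support(node, counts[split] / replicates)
    return tree


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy via Newick round-trip (support labels preserved)."""
    text = _to_newick(tree)
    return read_newick_with_support(io.StringIO(text))


def collapse_low_support(
    tree: dendropy.Tree, threshold: float = 0.70
) -> dendropy.Tree:
    """Contract internal edges with support strictly below ``threshold``.

    Edges without a support value (e.g. the root edge after rerooting, or
    user trees lacking labels) are retained.  The input tree is unchanged.
    """
    out = _clone(tree)
    doomed = []
    for node in out.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is not None and sup < threshold:
            doomed.append(node)
    for node in doomed:
        node.edge.collapse()
    return out


def root_tree(
    tree: dendropy.Tree,
    method: str = "midpoint",
    outgroup_ids: Iterable[str] | None = None,
) -> dendropy.Tree:
    """Root an (unrooted) tree at the midpoint or on an outgroup edge."""
    out = _clone(tree)
    out.is_rooted = True
    if method == "midpoint":
        lengths = [e.length or 0.0 for e in out.preorder_edge_iter()]
        if sum(lengths) == 0.0:
            return out  # degenerate zero-length tree: no midpoint exists
        try:
            out.reroot_at_midpoint(update_bipartitions=False)
        except AssertionError:
            # midpoint coincides with the current (multifurcating) seed
            # node; the tree is already midpoint-rooted as it stands
            return out
        seed = out.seed_node
        if seed.taxon is not None and seed.child_nodes():
            # midpoint fell exactly on a leaf node: demote the leaf back to
            # a zero-length child so the root stays unlabelled
            new_root = dendropy.Node()
            for ch in list(seed.child_nodes()):
                length = ch.edge.length
                seed.remove_child(ch)
                new_root.add_child(ch)
                ch.edge.length = length
            new_root.add_child(seed)
            seed.edge.length = 0.0
            out.seed_node = new_root
        return out
    if method != "outgroup":
        raise ValueError(f"unknown rooting method {method!r}")
    if not outgroup_ids:
        raise TreeError("outgroup rooting requires outgroup_ids")
    og = frozenset(outgroup_ids)
    all_tips = frozenset(lf.taxon.label for lf in out.leaf_node_iter())
    missing = og - all_tips
    if missing:
        raise TreeError(f"outgroup ids not in tree: {sorted(missing)}")
    leafsets = _leafsets(out)
    target = None
    for node, ls in leafsets.items():
        if node.parent_node is None:
            continue
        if ls == og or ls == all_tips - og:
            target = node
            break
    if target is None:
        raise TreeError("outgroup is not monophyletic in the unrooted tree")
    length = target.edge.length or 0.0
    out.reroot_at_edge(
        target.edge, length1=length / 2.0, length2=length / 2.0,
        update_bipartitions=False,
    )
    return out


def two_tip_tree(ids: Sequence[str], distance: float) -> dendropy.Tree:
    """Trivial rooted two-leaf tree (NJ proper requires >= 3 tips)."""
    if len(ids) != 2:
        raise TreeError("two_tip_tree needs exactly two ids")
    tns = dendropy.TaxonNamespace(list(ids))
    seed = dendropy.Node()
    for rid in ids:
        leaf = dendropy.Node(taxon=tns.get_taxon(rid))
        seed.add_child(leaf)
        leaf.edge.length = distance / 2.0
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = True
    return tree


def _to_newick(tree: dendropy.Tree) -> str:
    # refresh labels from support attributes before serializing
    for node in tree.preorder_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None and not node.is_leaf():
            node.label = f"{sup:.6g}"
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )


def write_newick_with_support(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(_to_newick(tree))


def read_newick_with_support(
    source, dialect: str = "label"
) -> dendropy.Tree:
    """Read Newick; supports from internal labels or bracket comments.

    ``source`` is a path or an open text handle.  ``dialect='label'`` reads
    supports from internal node labels; ``dialect='comment'`` from node
    comments such as ``[0.95]`` or ``[&support=0.95]``.
    """
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if hasattr(source, "read"):
        tree = dendropy.Tree.get(data=source.read(), **kwargs)
    else:
        tree = dendropy.Tree.get(path=str(source), **kwargs)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        raw = None
        if dialect == "label":
            raw = node.label
        elif dialect == "comment":
            raw = node.annotations.get_value("support", None)
            if raw is None:
                for comment in node.comments or []:
                    m = _SUPPORT_COMMENT.search(comment)
                    if m:
                        raw = m.group(1)
                        break
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        if raw is None:
            continue
        try:
            val = float(raw)
        except (TypeError, ValueError):
            continue
        node.support = val / 100.0 if val > 1.0 else val
    return tree
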