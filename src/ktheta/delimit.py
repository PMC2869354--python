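"""Recursive K/theta (4x) species delimitation over a supported tree.

The criterion: two sister clades are samples from distinct
evolutionary-genetic species when the mean corrected between-clade
divergence K exceeds m * theta, where theta is the larger of the two
within-clade estimates and the multiplier m depends on the sample sizes
(4.0 normally, 4.1 for a 2-vs-2 comparison, 4.3 when a singlet faces a
small sister).  The pass condition is strict (ratio exactly equal to the
multiplier merges).

Traversal is post-order: at every internal node, children that fail the
test against their closest sister group are merged into one candidate
clade whose diversity is recomputed over the union; children that pass
become species.  At polytomies each child is tested against the sibling
with the smallest mean corrected distance K (ties broken by the
lexicographically smallest clade label, a clade's label being its smallest
tip id).  Once any child subtree has split into species, no merging across
that node is attempted: remaining unsplit children are finalized as
species, with their sister test logged as evidence.

Two lone tips meeting at an internal bifurcation (a cherry) are below the
testing level — tests start at next-to-terminal clades — so they merge
silently into a two-member candidate judged by the parent's test.  Where a
singleton-vs-singleton verdict cannot be deferred (polytomy siblings, or a
two-tip root), theta rests entirely on the pooled zero-diversity floor and
the decision is flagged as low-power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .alignment import AlignedSequenceSet, PairwiseDistanceMatrix
from .diversity import CladeDiversity, clade_diversity, theta_zero_upper_bound
from .errors import TreeError, UndecidableError

__all__ = [
    "KThetaDecision",
    "SpeciesRecord",
    "SpeciesPartition",
    "multiplier_for",
    "ktheta_test",
    "delimit",
    "pairwise_histogram",
    "lineages_through_time",
    "Histogram",
]


def multiplier_for(n1: int, n2: int) -> tuple[float, tuple[str, ...]]:
    """K/theta multiplier for sister sample sizes (order-insensitive).

    Returns ``(multiplier, flags)``; the 1-vs-1 comparison carries a
    low-power flag because neither clade provides a theta estimate.
    """
    n1, n2 = max(n1, n2), min(n1, n2)
    if n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if n2 >= 2:
        return (4.1, ()) if n1 == 2 else (4.0, ())
    # n2 == 1 (singlet)
    if n1 >= 5:
        return 4.0, ()
    if n1 >= 2:
        return 4.3, ()
    return 4.3, ("low-power-1v1",)


@dataclass(frozen=True)
class KThetaDecision:
    """One sister-clade comparison with its full evidence trail."""

    clade_a_tips: frozenset[str]
    clade_b_tips: frozenset[str]
    n1: int
    n2: int
    theta_used: float
    D_between: float
    K_between: float
    multiplier: float
    ratio: float
    verdict: str  # "distinct" | "merged"
    flags: tuple[str, ...] = ()

    @property
    def label_a(self) -> str:
        return min(self.clade_a_tips)

    @property
    def label_b(self) -> str:
        return min(self.clade_b_tips)


def ktheta_test(
    div_a: CladeDiversity,
    div_b: CladeDiversity,
    matrix: PairwiseDistanceMatrix,
    multiplier_scale: float = 1.0,
    fallback_L: int | None = None,
) -> KThetaDecision:
    """Apply the K/theta criterion to two disjoint clades.

    ``theta_used`` is the larger of the defined sister thetas, floored by
    the 95% zero-diversity bound at the pooled sample size (see
    :func:`ktheta.diversity.theta_zero_upper_bound`).  If neither clade
    has a theta (two singletons) the test is undecidable unless
    ``fallback_L`` supplies the alignment length for the floor.
    """
    if div_a.tip_ids & div_b.tip_ids:
        raise ValueError("clades overlap")
    D_between, K_between = matrix.mean_cross(div_a.tip_ids, div_b.tip_ids)
    flags: list[str] = []
    point_thetas = [d.theta for d in (div_a, div_b) if d.has_theta]
    if not point_thetas and fallback_L is None:
        raise UndecidableError(
            "both clades are singletons: no within-clade theta available"
        )
    L = fallback_L if fallback_L is not None else max(div_a.L, div_b.L)
    # floor: the largest theta that could hide behind zero observed
    # diversity in a single population of the pooled sample size (95%
    # one-sided); shallow sisters would otherwise contribute near-zero
    # thetas and overstate split confidence far beyond the intended 5%
    pooled_floor = theta_zero_upper_bound(div_a.n + div_b.n, L)
    theta_used = max(point_thetas + [pooled_floor])
    if theta_used == pooled_floor and (
        not point_thetas or pooled_floor > max(point_thetas)
    ):
        flags.append("theta-floor")
    n1, n2 = max(div_a.n, div_b.n), min(div_a.n, div_b.n)
    m, mflags = multiplier_for(n1, n2)
    flags.extend(mflags)
    m *= multiplier_scale
    ratio = K_between / theta_used
    verdict = "distinct" if ratio > m else "merged"
    return KThetaDecision(
        div_a.tip_ids,
        div_b.tip_ids,
        n1,
        n2,
        theta_used,
        D_between,
        K_between,
        m,
        ratio,
        verdict,
        tuple(flags),
    )


@dataclass(frozen=True)
class SpeciesRecord:
    label: str
    tips: frozenset[str]
    diversity: CladeDiversity

    @property
    def is_singlet(self) -> bool:
        return len(self.tips) == 1


@dataclass
class SpeciesPartition:
    """Delimitation result: disjoint species covering every tip."""

    species: list[SpeciesRecord]
    decisions: list[KThetaDecision]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.species:
            if rec.tips & seen:
                raise ValueError("species tip sets overlap")
            seen |= rec.tips

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def all_tips(self) -> frozenset[str]:
        out: set[str] = set()
        for rec in self.species:
            out |= rec.tips
        return frozenset(out)

    def assignment(self) -> dict[str, str]:
        return {tip: rec.label for rec in self.species for tip in rec.tips}

    def tip_sets(self) -> set[frozenset[str]]:
        return {rec.tips for rec in self.species}


class _Delimiter:
    def __init__(
        self,
        matrix: PairwiseDistanceMatrix,
        multiplier_scale: float,
    ) -> None:
        self.matrix = matrix
        self.scale = multiplier_scale
        self.decisions: list[KThetaDecision] = []

    # clade label for deterministic tie-breaking
    @staticmethod
    def _label(div: CladeDiversity) -> str:
        return min(div.tip_ids)

    def _test(self, a: CladeDiversity, b: CladeDiversity) -> KThetaDecision:
        return ktheta_test(
            a, b, self.matrix,
            multiplier_scale=self.scale,
            fallback_L=self.matrix.L,
        )

    def _closest_sibling(
        self, x: CladeDiversity, others: Sequence[CladeDiversity]
    ) -> CladeDiversity:
        """Sibling with the smallest mean corrected K (ties: smallest label)."""
        best = None
        best_key = None
        for y in others:
            _, k = self.matrix.mean_cross(x.tip_ids, y.tip_ids)
            key = (k, self._label(y))
            if best_key is None or key < best_key:
                best, best_key = y, key
        assert best is not None
        return best

    def _merge(self, a: CladeDiversity, b: CladeDiversity) -> CladeDiversity:
        return clade_diversity(self.matrix, a.tip_ids | b.tip_ids)

    def _resolve_candidates(
        self, groups: list[CladeDiversity], at_root: bool
    ) -> tuple[list[CladeDiversity], bool]:
        """Merge loop among sibling candidate clades at one node.

        Returns the surviving groups and whether the node split (>= 2
        groups remained mutually distinct).
        """
        groups = sorted(groups, key=self._label)
        # a cherry at an internal bifurcation is below the testing level
        # (tests start at next-to-terminal clades): merge silently and let
        # the parent judge the pair as a two-member clade
        if (
            not at_root
            and len(groups) == 2
            and all(g.n == 1 for g in groups)
        ):
            return [self._merge(groups[0], groups[1])], False
        while len(groups) > 1:
            applied = None
            for x in groups:
                others = [g for g in groups if g is not x]
                y = self._closest_sibling(x, others)
                dec = self._test(x, y)
                if dec.verdict == "merged":
                    applied = (x, y, dec)
                    break
            if applied is None:
                break
            x, y, dec = applied
            self.decisions.append(dec)
            groups = [g for g in groups if g is not x and g is not y]
            groups.append(self._merge(x, y))
            groups.sort(key=self._label)
        if len(groups) == 1:
            return groups, False
        # stable: log each surviving pair's evidence once
        logged: set[frozenset[str]] = set()
        for x in groups:
            others = [g for g in groups if g is not x]
            y = self._closest_sibling(x, others)
            key = frozenset({self._label(x), self._label(y)})
            if key in logged:
                continue
            logged.add(key)
            self.decisions.append(self._test(x, y))
        return groups, True

    def resolve(
        self, node: dendropy.Node, at_root: bool = False
    ) -> tuple[list[CladeDiversity], bool]:
        if node.is_leaf():
            return [clade_diversity(self.matrix, {node.taxon.label})], False
        child_results = [self.resolve(ch) for ch in node.child_nodes()]
        if len(child_results) == 1:  # unifurcation (e.g. rooted two-tip stub)
            return child_results[0]
        locked: list[CladeDiversity] = []
        candidates: list[CladeDiversity] = []
        child_wholes: list[CladeDiversity] = []
        any_split = False
        for (groups, split), ch in zip(child_results, node.child_nodes()):
            tips: set[str] = set()
            for g in groups:
                tips |= g.tip_ids
            child_wholes.append(clade_diversity(self.matrix, tips))
            if split:
                any_split = True
                locked.extend(groups)
            else:
                candidates.append(groups[0])
        if not any_split:
            return self._resolve_candidates(candidates, at_root)
        # a child already contains distinct species: no merging across this
        # node; unsplit children become species, with their sister test
        # (against the closest whole sibling clade) logged as evidence
        for x in candidates:
            others = [w for w in child_wholes if not (w.tip_ids & x.tip_ids)]
            y = self._closest_sibling(x, others)
            dec = self._test(x, y)
            dec = KThetaDecision(
                dec.clade_a_tips, dec.clade_b_tips, dec.n1, dec.n2,
                dec.theta_used, dec.D_between, dec.K_between,
                dec.multiplier, dec.ratio, dec.verdict,
                dec.flags + ("sister-contains-species",),
            )
            self.decisions.append(dec)
        return locked + candidates, True


def delimit(
    tree: dendropy.Tree,
    matrix: PairwiseDistanceMatrix,
    aln: AlignedSequenceSet | None = None,
    multiplier_scale: float = 1.0,
) -> SpeciesPartition:
    """Partition the tree's tips into evolutionary-genetic species.

    ``tree`` must be rooted and already collapsed at the desired support
    threshold (see :func:`ktheta.njtree.collapse_low_support`); its tip set
    must match the distance matrix ids.
    """
    tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if tree_tips != set(matrix.ids):
        raise TreeError(
            "tree tips do not match distance matrix ids: "
            f"only-in-tree={sorted(tree_tips - set(matrix.ids))[:5]}, "
            f"only-in-matrix={sorted(set(matrix.ids) - tree_tips)[:5]}"
        )
    if aln is not None and set(aln.ids) != tree_tips:
        raise TreeError("alignment ids do not match tree tips")
    engine = _Delimiter(matrix, multiplier_scale)
    groups, _ = engine.resolve(tree.seed_node, at_root=True)
    # stable labels in tree tip order
    tip_order = {lf.taxon.label: i for i, lf in enumerate(tree.leaf_node_iter())}
    groups = sorted(groups, key=lambda g: min(tip_order[t] for t in g.tip_ids))
    width = len(str(len(groups)))
    species = [
        SpeciesRecord(f"sp{i + 1:0{width}d}", g.tip_ids, g)
        for i, g in enumerate(groups)
    ]
    part = SpeciesPartition(species, engine.decisions)
    if part.all_tips != frozenset(tree_tips):
        raise AssertionError("partition does not cover all tips")
    return part


@dataclass(frozen=True)
class Histogram:
    bin_width: float
    counts: np.ndarray  # total counts per bin, bin i = [i*w, (i+1)*w)
    within_counts: np.ndarray | None = None
    between_counts: np.ndarray | None = None

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(len(self.counts) + 1) * self.bin_width


def pairwise_histogram(
    matrix: PairwiseDistanceMatrix,
    bin_width: float = 0.01,
    use: str = "D",
    partition: SpeciesPartition | None = None,
) -> Histogram:
    """Frequency distribution of pairwise differences in half-open bins.

    With a partition supplied, counts are additionally split into
    within-species and between-species pairs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = matrix.condensed(use=use)
    idx = np.floor(values / bin_width).astype(int)
    nbins = int(idx.max()) + 1 if idx.size else 1
    counts = np.bincount(idx, minlength=nbins)
    within = between = None
    if partition is not None:
        assign = partition.assignment()
        iu, ju = np.triu_indices(matrix.n, k=1)
        same = np.array(
            [assign[matrix.ids[i]] == assign[matrix.ids[j]] for i, j in zip(iu, ju)]
        )
        within = np.bincount(idx[same], minlength=nbins)
        between = np.bincount(idx[~same], minlength=nbins)
    return Histogram(bin_width, counts, within, between)


def lineages_through_time(tree: dendropy.Tree) -> list[tuple[float, int]]:
    """(time, lineage count) at successive internal-node depths.

    Times are root-to-node path lengths; simultaneous nodes are merged
    into a single step.  The final count equals the number of tips.
    """
    depths: dict[dendropy.Node, float] = {}
    events: list[tuple[float, int]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            if node.edge.length is None:
                raise TreeError("tree has missing branch lengths")
            depths[node] = depths[node.parent_node] + node.edge.length
        if not node.is_leaf():
            events.append((depths[node], len(node.child_nodes()) - 1))
    events.sort(key=lambda e: e[0])
    out: list[tuple[float, int]] = []
    count = 1
    for t, inc in events:
        count += inc
        if out and out[-1][0] == t:
            out[-1] = (t, count)
        else:
            out.append((t, count))
    return out
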