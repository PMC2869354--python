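import io
import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktheta.alignment import AlignedSequenceSet, PairwiseDistanceMatrix, distance_matrix
from ktheta.delimit import (
    delimit,
    ktheta_test,
    lineages_through_time,
    multiplier_for,
    pairwise_histogram,
)
from ktheta.diversity import CladeDiversity, clade_diversity, nucleotide_diversity, theta_from_pi
from ktheta.errors import TreeError, UndecidableError
from ktheta.njtree import read_newick_with_support
from ktheta.pipeline import delimit_alignment

from conftest import mutate, random_sequence


def matrix_from_D(ids, D, L=591, K=None):
    D = np.asarray(D, dtype=float)
    K = D.copy() if K is None else np.asarray(K, dtype=float)
    return PairwiseDistanceMatrix(
        tuple(ids), D, K, np.full(D.shape, L, dtype=int), L=L, model="none"
    )


def block_matrix(ids_a, ids_b, within_a, within_b, between, L=591):
    ids = list(ids_a) + list(ids_b)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both_a = ids[i] in ids_a and ids[j] in ids_a
            both_b = ids[i] in ids_b and ids[j] in ids_b
            D[i, j] = D[j, i] = within_a if both_a else within_b if both_b else between
    return matrix_from_D(ids, D, L=L)


class TestMultiplierFor:
    @pytest.mark.parametrize(
        "n1,n2,expected",
        [
            (3, 2, 4.0),
            (10, 2, 4.0),
            (3, 3, 4.0),
            (2, 2, 4.1),
            (5, 1, 4.0),
            (23, 1, 4.0),
            (2, 1, 4.3),
            (3, 1, 4.3),
            (4, 1, 4.3),
            (1, 1, 4.3),
        ],
    )
    def test_table(self, n1, n2, expected):
        m, _ = multiplier_for(n1, n2)
        assert m == expected

    def test_order_insensitive(self):
        assert multiplier_for(1, 4) == multiplier_for(4, 1)

    def test_one_vs_one_flagged(self):
        _, flags = multiplier_for(1, 1)
        assert "low-power-1v1" in flags

    def test_invalid(self):
        with pytest.raises(ValueError):
            multiplier_for(3, 0)


class TestKThetaTest:
    def _clade(self, tips, n, pi, L=591):
        d = pi * (n - 1) / n
        return CladeDiversity(frozenset(tips), n, d, pi, theta_from_pi(pi), L)

    def test_worked_worm_example(self):
        """Between-clade divergence 17.7%, within diversities 0.6%/1.3%,
        samples 23 and 7: ratio ~13.4, clearly distinct."""
        tips_a = {f"I{i}" for i in range(23)}
        tips_b = {f"II{i}" for i in range(7)}
        m = block_matrix(sorted(tips_a), sorted(tips_b), 0.006, 0.013, 0.177)
        div_a = self._clade(tips_a, 23, 0.006)
        div_b = self._clade(tips_b, 7, 0.013)
        dec = ktheta_test(div_a, div_b, m)
        assert dec.theta_used == pytest.approx(0.0132296, rel=1e-4)
        assert dec.ratio == pytest.approx(13.38, abs=0.01)
        assert dec.multiplier == 4.0
        assert dec.verdict == "distinct"

    def test_ratio_three_point_nine_merges(self):
        tips_a, tips_b = {"a1", "a2", "a3"}, {"b1", "b2"}
        m = block_matrix(sorted(tips_a), sorted(tips_b), 0.0, 0.0, 0.039)
        pi = 0.01 / (1 + 4 * 0.01 / 3)  # so that theta == 0.01 exactly
        div_a = self._clade(tips_a, 3, pi)
        div_b = self._clade(tips_b, 2, pi)
        dec = ktheta_test(div_a, div_b, m)
        assert dec.multiplier == 4.0
        assert dec.ratio == pytest.approx(3.9, abs=1e-6)
        assert dec.verdict == "merged"

    def test_two_vs_two_threshold(self):
        tips_a, tips_b = {"a1", "a2"}, {"b1", "b2"}
        theta = 0.01
        m = block_matrix(sorted(tips_a), sorted(tips_b), 0.0, 0.0, 4.05 * theta)
        pi = theta / (1 + 4 * theta / 3)  # invert so theta_from_pi(pi) == theta
        div_a = self._clade(tips_a, 2, pi)
        div_b = self._clade(tips_b, 2, pi)
        dec = ktheta_test(div_a, div_b, m)
        assert dec.multiplier == 4.1
        assert dec.ratio == pytest.approx(4.05, rel=1e-9)
        assert dec.verdict == "merged"

    def test_two_singletons_undecidable_without_L(self):
        m = block_matrix(["a"], ["b"], 0.0, 0.0, 0.2)
        div_a = clade_diversity(m, {"a"})
        div_b = clade_diversity(m, {"b"})
        with pytest.raises(UndecidableError):
            ktheta_test(div_a, div_b, m)

    def test_two_singletons_with_floor(self):
        m = block_matrix(["a"], ["b"], 0.0, 0.0, 0.2)
        dec = ktheta_test(
            clade_diversity(m, {"a"}), clade_diversity(m, {"b"}), m, fallback_L=591
        )
        assert "theta-floor" in dec.flags
        assert dec.verdict == "distinct"

    def test_overlapping_clades_rejected(self):
        m = block_matrix(["a", "b"], ["c"], 0.01, 0.0, 0.2)
        with pytest.raises(ValueError):
            ktheta_test(
                clade_diversity(m, {"a", "b"}), clade_diversity(m, {"b", "c"}), m
            )


def star_tree(ids):
    tns = dendropy.TaxonNamespace(list(ids))
    seed = dendropy.Node()
    for rid in ids:
        leaf = dendropy.Node(taxon=tns.get_taxon(rid))
        seed.add_child(leaf)
        leaf.edge.length = 0.1
    t = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    t.is_rooted = True
    return t


class TestDelimit:
    def test_balanced_four_tip_two_species(self):
        # within-pair D = 0.01, between D = 0.20, fully supported tree
        m = block_matrix(["a1", "a2"], ["b1", "b2"], 0.01, 0.01, 0.20)
        tree = read_newick_with_support(
            io.StringIO("((a1:0.005,a2:0.005)1.0:0.1,(b1:0.005,b2:0.005)1.0:0.1);")
        )
        part = delimit(tree, m)
        assert part.tip_sets() == {
            frozenset({"a1", "a2"}),
            frozenset({"b1", "b2"}),
        }
        # hand value: theta = theta_from_pi(0.02) ~ 0.0205; 0.2/0.0205 ~ 9.7 > 4.1
        final = [d for d in part.decisions if d.verdict == "distinct"]
        assert len(final) == 1
        assert final[0].ratio == pytest.approx(
            0.20 / theta_from_pi(nucleotide_diversity(0.01, 2, 591)), rel=1e-9
        )

    def test_six_similar_tips_one_species(self):
        ids = [f"t{i}" for i in range(6)]
        D = np.full((6, 6), 0.005)
        np.fill_diagonal(D, 0.0)
        m = matrix_from_D(ids, D)
        tree = star_tree(ids)
        part = delimit(tree, m)
        assert part.n_species == 1
        assert part.species[0].tips == frozenset(ids)

    def test_three_star_distant_singlets(self):
        ids = ["x", "y", "z"]
        D = np.full((3, 3), 0.20)
        np.fill_diagonal(D, 0.0)
        m = matrix_from_D(ids, D)
        part = delimit(star_tree(ids), m)
        assert part.n_species == 3
        assert all(rec.is_singlet for rec in part.species)
        assert any("theta-floor" in d.flags for d in part.decisions)

    def test_tip_matrix_mismatch(self):
        m = block_matrix(["a1", "a2"], ["b1"], 0.01, 0.0, 0.2)
        with pytest.raises(TreeError):
            delimit(star_tree(["a1", "a2", "zzz"]), m)

    def test_determinism(self, two_block_alignment):
        r1 = delimit_alignment(two_block_alignment, bootstrap_replicates=25, seed=9)
        r2 = delimit_alignment(two_block_alignment, bootstrap_replicates=25, seed=9)
        assert r1.partition.assignment() == r2.partition.assignment()
        assert [
            (d.clade_a_tips, d.clade_b_tips, d.ratio, d.verdict)
            for d in r1.partition.decisions
        ] == [
            (d.clade_a_tips, d.clade_b_tips, d.ratio, d.verdict)
            for d in r2.partition.decisions
        ]

    def test_two_blocks_recovered(self, two_block_alignment):
        res = delimit_alignment(two_block_alignment, bootstrap_replicates=50, seed=1)
        assert res.partition.tip_sets() == {
            frozenset({"a1", "a2", "a3"}),
            frozenset({"b1", "b2", "b3"}),
        }

    def test_two_sequence_alignment(self):
        aln = AlignedSequenceSet.from_pairs(
            [("p", "A" * 300), ("q", "C" * 90 + "A" * 210)]
        )
        res = delimit_alignment(aln)
        assert res.partition.n_species == 2
        assert "theta-floor" in res.partition.decisions[0].flags

    def test_two_similar_sequences_merge(self):
        aln = AlignedSequenceSet.from_pairs(
            [("p", "A" * 300), ("q", "C" * 3 + "A" * 297)]
        )
        res = delimit_alignment(aln)
        assert res.partition.n_species == 1


def random_alignment(rng, n=None, L=80):
    n = n or rng.integers(4, 9)
    base = random_sequence(rng, L)
    recs = []
    for i in range(n):
        k = int(rng.integers(0, L // 3))
        pos = rng.choice(L, size=k, replace=False)
        recs.append((f"s{i}", mutate(base, pos)))
    return AlignedSequenceSet.from_pairs(recs)


class TestPartitionProperties:
    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_partition_covers_all_tips(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng)
        res = delimit_alignment(aln, bootstrap_replicates=0)
        assert res.partition.all_tips == frozenset(aln.ids)
        labels = res.partition.assignment()
        assert set(labels) == set(aln.ids)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_multiplier_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng)
        base = delimit_alignment(aln, bootstrap_replicates=0, multiplier_scale=1.0)
        stricter = delimit_alignment(aln, bootstrap_replicates=0, multiplier_scale=1.5)
        assert stricter.partition.n_species <= base.partition.n_species


class TestPairwiseHistogram:
    def test_identical_sequences_single_bin(self):
        m = matrix_from_D(["a", "b", "c"], np.zeros((3, 3)))
        h = pairwise_histogram(m, 0.01)
        assert h.counts.tolist() == [3]

    def test_direct_binning(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = 0.005
        D[0, 2] = D[2, 0] = 0.015
        D[1, 2] = D[2, 1] = 0.25
        h = pairwise_histogram(matrix_from_D(["a", "b", "c"], D), 0.01)
        assert h.counts[0] == 1 and h.counts[1] == 1 and h.counts[25] == 1
        assert h.counts.sum() == 3

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_counts_conserved(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng)
        m = distance_matrix(aln, model="none")
        h = pairwise_histogram(m, 0.01)
        assert h.counts.sum() == m.n * (m.n - 1) // 2

    def test_within_between_split(self, two_block_alignment):
        res = delimit_alignment(two_block_alignment, bootstrap_replicates=0)
        h = res.histogram
        assert (h.within_counts + h.between_counts == h.counts).all()

    def test_bad_bin_width(self):
        m = matrix_from_D(["a", "b"], [[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError):
            pairwise_histogram(m, 0.0)


class TestLineagesThroughTime:
    def _tree(self, text):
        return read_newick_with_support(io.StringIO(text))

    def test_balanced_four_tips(self):
        t = self._tree("((a:1,b:1):1,(c:1,d:1):1);")
        assert lineages_through_time(t) == [(0.0, 2), (1.0, 4)]

    def test_caterpillar(self):
        t = self._tree("(((a:1,b:1):1,c:2):1,d:3);")
        ltt = lineages_through_time(t)
        assert [c for _, c in ltt] == [2, 3, 4]
        assert [round(x, 6) for x, _ in ltt] == [0.0, 1.0, 2.0]

    def test_final_count_is_n(self):
        t = self._tree("((a:1,b:1):1,(c:0.5,(d:0.2,e:0.2):0.3):1.5);")
        assert lineages_through_time(t)[-1][1] == 5

    def test_missing_lengths_error(self):
        t = self._tree("((a,b),(c,d));")
        with pytest.raises(TreeError):
            lineages_through_time(t)
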