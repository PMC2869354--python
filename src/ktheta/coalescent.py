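"""Kingman-coalescent Monte-Carlo engine and synthetic-sequence generator.

Time unit convention: one unit = Ne generations for an effectively haploid
locus, so any two lineages in the same population coalesce at rate 1 per
unit time.  With this scaling theta = 2*Ne*mu per site, the divergence time
tau of two populations is dimensionless (t/Ne), and the between-population
corrected distance satisfies K/theta ~= tau.

Genealogies are simulated with msprime (population size 1, ploidy 1);
"whole population" reciprocal monophyly is approximated by tracking B
background lineages per population (finite B can only overestimate the
population-level probability).  Mutations are dropped on branches as a
Poisson process with per-site rate theta/2 per unit time under Jukes-Cantor
site evolution, so the expected within-population pairwise difference is
~theta before saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import msprime
import numpy as np
import tskit
from scipy.stats import beta

from .alignment import AlignedSequenceSet
from .errors import SimulationError

__all__ = [
    "CoalescentConfig",
    "SimulatedGenealogy",
    "RMEstimate",
    "sample_tmrca",
    "tmrca_mean_exact",
    "two_population_genealogy",
    "genealogies",
    "reciprocal_monophyly",
    "population_reciprocal_monophyly",
    "conditional_rm_probability",
    "simulate_sequences",
    "simulate_two_population_alignment",
]


def tmrca_mean_exact(n: int) -> float:
    """Closed-form mean TMRCA, 2*(1 - 1/n), in Ne-generation units."""
    if n < 2:
        raise ValueError("TMRCA needs n >= 2")
    return 2.0 * (1.0 - 1.0 / n)


def sample_tmrca(
    n: int, replicates: int = 100_000, seed: int | None = None
) -> np.ndarray:
    """Simulate single-population TMRCAs as sums of exponential epochs.

    Each replicate is sum_{k=2}^{n} T_k with T_k ~ Exp(k*(k-1)/2); the
    expectation approaches 2 Ne generations for large n.
    """
    if n < 2:
        raise ValueError("TMRCA needs n >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ks = np.arange(2, n + 1, dtype=float)
    rates = ks * (ks - 1.0) / 2.0
    draws = rng.exponential(scale=1.0 / rates, size=(replicates, len(ks)))
    return draws.sum(axis=1)


@dataclass(frozen=True)
class CoalescentConfig:
    """Two-population divergence scenario in Ne-generation units."""

    tau: float
    n1: int
    n2: int
    background_per_pop: int | None = None
    theta: float = 0.0
    L: int = 1
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise SimulationError(f"tau must be >= 0, got {self.tau}")
        if self.n1 < 1 or self.n2 < 1:
            raise SimulationError("sample sizes must be >= 1")
        if self.theta < 0:
            raise SimulationError("theta must be >= 0")
        if self.L < 1:
            raise SimulationError("sequence length must be >= 1")
        if self.replicates < 1:
            raise SimulationError("replicates must be >= 1")
        if (
            self.background_per_pop is not None
            and self.background_per_pop < max(self.n1, self.n2)
        ):
            raise SimulationError(
                "background_per_pop must be >= max(n1, n2)"
            )

    @property
    def B(self) -> int:
        if self.background_per_pop is None:
            return max(self.n1, self.n2)
        return self.background_per_pop


@dataclass(frozen=True)
class SimulatedGenealogy:
    """A single simulated genealogy over two (possibly merged) populations.

    ``pop1_nodes``/``pop2_nodes`` are all sampled lineages per population;
    the first n1/n2 of each are the focal samples.
    """

    ts: tskit.TreeSequence
    pop1_nodes: tuple[int, ...]
    pop2_nodes: tuple[int, ...]
    n1: int
    n2: int

    @property
    def focal1(self) -> tuple[int, ...]:
        return self.pop1_nodes[: self.n1]

    @property
    def focal2(self) -> tuple[int, ...]:
        return self.pop2_nodes[: self.n2]

    @property
    def tree(self) -> tskit.Tree:
        return self.ts.first()

    def tip_label(self, node: int) -> str:
        if node in self.pop1_nodes:
            i = self.pop1_nodes.index(node)
            return f"A{i + 1}" if i < self.n1 else f"bgA{i + 1 - self.n1}"
        if node in self.pop2_nodes:
            i = self.pop2_nodes.index(node)
            return f"B{i + 1}" if i < self.n2 else f"bgB{i + 1 - self.n2}"
        raise KeyError(node)

    def newick(self, focal_only: bool = False) -> str:
        ts = self.ts
        if focal_only:
            keep = list(self.focal1 + self.focal2)
            ts = self.ts.simplify(samples=keep, filter_nodes=True)
            labels = {
                i: (f"A{i + 1}" if i < self.n1 else f"B{i + 1 - self.n1}")
                for i in range(self.n1 + self.n2)
            }
        else:
            labels = {u: self.tip_label(u) for u in ts.samples()}
        return ts.first().as_newick(node_labels=labels)


def _demography(tau: float) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="p1", initial_size=1)
    dem.add_population(name="p2", initial_size=1)
    dem.add_population(name="anc", initial_size=1)
    dem.add_population_split(time=tau, derived=["p1", "p2"], ancestral="anc")
    return dem


def _sim_iter(config: CoalescentConfig, replicates: int, seed: int | None):
    B = config.B
    common = dict(
        ploidy=1,
        sequence_length=config.L,
        num_replicates=replicates,
        random_seed=None if seed is None else max(1, int(seed)),
    )
    if config.tau == 0:
        # model collapse: a single panmictic population of 2B lineages
        return msprime.sim_ancestry(
            samples=2 * B, population_size=1, **common
        )
    return msprime.sim_ancestry(
        samples={"p1": B, "p2": B}, demography=_demography(config.tau), **common
    )


def _wrap(ts: tskit.TreeSequence, config: CoalescentConfig) -> SimulatedGenealogy:
    B = config.B
    samples = list(ts.samples())
    return SimulatedGenealogy(
        ts,
        tuple(samples[:B]),
        tuple(samples[B : 2 * B]),
        config.n1,
        config.n2,
    )


def genealogies(config: CoalescentConfig) -> Iterator[SimulatedGenealogy]:
    """Stream ``config.replicates`` independent genealogies."""
    for ts in _sim_iter(config, config.replicates, config.seed):
        yield _wrap(ts, config)


def two_population_genealogy(
    config: CoalescentConfig, seed: int | None = None
) -> SimulatedGenealogy:
    """One genealogy over B + B lineages with the focal samples marked."""
    seed = config.seed if seed is None else seed
    ts = next(iter(_sim_iter(config, 1, seed)))
    return _wrap(ts, config)


def _is_descendant(tree: tskit.Tree, u: int, anc: int) -> bool:
    while u != tskit.NULL:
        if u == anc:
            return True
        u = tree.parent(u)
    return False


def _exclusive(tree: tskit.Tree, group, other) -> bool:
    """True if ``group``'s MRCA subtree contains no member of ``other``."""
    if len(group) == 1:
        return True
    m = tree.mrca(*group)
    return not any(_is_descendant(tree, o, m) for o in other)


def reciprocal_monophyly(
    genealogy: SimulatedGenealogy | tskit.Tree,
    tip_subset_a,
    tip_subset_b,
) -> bool:
    """Reciprocal monophyly of two disjoint tip subsets, restricted to
    their union (other lineages in the genealogy are ignored).

    A singleton subset is monophyletic by convention, so the decision then
    rests on the partner subset excluding the singleton.
    """
    tree = genealogy.tree if isinstance(genealogy, SimulatedGenealogy) else genealogy
    a = list(tip_subset_a)
    b = list(tip_subset_b)
    if not a or not b:
        raise ValueError("tip subsets must be non-empty")
    if set(a) & set(b):
        raise ValueError("tip subsets must be disjoint")
    return _exclusive(tree, a, b) and _exclusive(tree, b, a)


def population_reciprocal_monophyly(genealogy: SimulatedGenealogy) -> bool:
    """RM of the two full background lineage sets (the 'populations')."""
    tree = genealogy.tree
    B = len(genealogy.pop1_nodes)
    m1 = tree.mrca(*genealogy.pop1_nodes)
    if tree.num_samples(m1) != B:
        return False
    m2 = tree.mrca(*genealogy.pop2_nodes)
    return tree.num_samples(m2) == B


@dataclass(frozen=True)
class RMEstimate:
    """Monte-Carlo estimate of conditional population reciprocal monophyly."""

    p_sample_rm: float
    p_pop_rm_given_sample_rm: float
    ci_low: float
    ci_high: float
    n_conditioned: int
    n_success: int
    replicates: int


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.isf(alpha / 2, k + 1, n - k))
    return lo, hi


def conditional_rm_probability(
    config: CoalescentConfig, min_conditioned: int = 100
) -> RMEstimate:
    """P(populations reciprocally monophyletic | focal samples are).

    The conditioning event is reciprocal monophyly of the n1 + n2 focal
    samples restricted to their union; for a singlet focal sample the event
    is the larger sample forming a clade exclusive of the singlet.  Widens
    (doubles the replicate count, with a warning) until at least
    ``min_conditioned`` conditioning events are seen.
    """
    import warnings

    total = 0
    conditioned = 0
    success = 0
    reps = config.replicates
    seed = config.seed
    rounds = 0
    while True:
        for g in genealogies(replace(config, replicates=reps, seed=seed)):
            total += 1
            if not reciprocal_monophyly(g, g.focal1, g.focal2):
                continue
            conditioned += 1
            if population_reciprocal_monophyly(g):
                success += 1
        if conditioned >= min_conditioned:
            break
        rounds += 1
        if rounds > 6:
            raise SimulationError(
                f"only {conditioned} conditioning events in {total} replicates;"
                " increase replicates or tau"
            )
        warnings.warn(
            f"only {conditioned} conditioning events in {total} replicates;"
            " doubling the replicate count",
            stacklevel=2,
        )
        seed = None if seed is None else seed + 7_919 * rounds
        reps *= 2
    lo, hi = _clopper_pearson(success, conditioned)
    return RMEstimate(
        p_sample_rm=conditioned / total,
        p_pop_rm_given_sample_rm=success / conditioned,
        ci_low=lo,
        ci_high=hi,
        n_conditioned=conditioned,
        n_success=success,
        replicates=total,
    )


_NUCS = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_sequences(
    genealogy: SimulatedGenealogy,
    theta: float,
    L: int,
    seed: int | None = None,
    focal_only: bool = True,
) -> AlignedSequenceSet:
    """Drop Jukes-Cantor mutations on the genealogy and emit an alignment.

    Per-site mutation rate is theta/2 per Ne generation.  With
    ``focal_only`` (default) only the focal samples appear in the output,
    labelled A1..An1 and B1..Bn2.
    """
    if theta < 0 or L < 1:
        raise ValueError("need theta >= 0 and L >= 1")
    ts = genealogy.ts
    if ts.sequence_length != L:
        raise SimulationError(
            f"genealogy was simulated for L={int(ts.sequence_length)},"
            f" not L={L}; set L in the CoalescentConfig"
        )
    mts = msprime.sim_mutations(
        ts,
        rate=theta / 2.0,
        model=msprime.JC69(),
        random_seed=None if seed is None else max(1, int(seed)),
    )
    rng = np.random.default_rng(seed)
    n_samples = mts.num_samples
    # stationary JC root states, overwritten wherever variants exist
    base = _NUCS[rng.integers(0, 4, size=L)]
    seqs = np.tile(base, (n_samples, 1))
    for var in mts.variants():
        site = int(var.site.position)
        alleles = np.array(
            [a.encode()[0] if a else ord("N") for a in var.alleles], dtype=np.uint8
        )
        seqs[:, site] = alleles[var.genotypes]
    if focal_only:
        rows = list(genealogy.focal1) + list(genealogy.focal2)
        labels = [f"A{i + 1}" for i in range(genealogy.n1)] + [
            f"B{i + 1}" for i in range(genealogy.n2)
        ]
    else:
        rows = list(mts.samples())
        labels = [genealogy.tip_label(u) for u in rows]
    sample_index = {u: i for i, u in enumerate(mts.samples())}
    records = tuple(
        (label, seqs[sample_index[u]].tobytes().decode("ascii"))
        for label, u in zip(labels, rows)
    )
    return AlignedSequenceSet(records)


def simulate_two_population_alignment(
    config: CoalescentConfig, seed: int | None = None
) -> tuple[AlignedSequenceSet, dict[str, str], SimulatedGenealogy]:
    """Convenience fixture generator: alignment + true species assignment.

    Uses a genealogy over exactly the focal samples (background lineages do
    not affect the focal subtree's marginal distribution).
    """
    seed = config.seed if seed is None else seed
    cfg = replace(
        config,
        background_per_pop=max(config.n1, config.n2),
        seed=seed,
    )
    gen = two_population_genealogy(cfg)
    # keep only the focal rows; the extra background lineages (when
    # n1 != n2) are simply ignored downstream
    aln = simulate_sequences(
        gen, cfg.theta, cfg.L, seed=None if seed is None else seed + 1
    )
    truth = {f"A{i + 1}": "pop1" for i in range(cfg.n1)}
    truth.update({f"B{i + 1}": "pop2" for i in range(cfg.n2)})
    return aln, truth, gen
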