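# ktheta

Evolutionary-genetic species delimitation for asexual and clonal organisms
from single-locus alignments, via the K/θ ("4×") rule: two well-supported
sister clades are distinct species when their mean corrected divergence K
exceeds about four times θ = 2·Ne·μ estimated from within-clade diversity
(θ = π/(1 − 4π/3), π from the mean pairwise difference with the n/(n−1)
sample-size correction).  Under neutral coalescence, K/θ estimates the
divergence time in Ne-generation units, so K > 4θ means a gap too deep to
be a transient product of drift at ~95% confidence.

The package also contains a Kingman-coalescent Monte-Carlo engine
(msprime-backed) that validates the rule's probability claims — TMRCA
moments and quantiles, conditional reciprocal-monophyly probabilities for
small samples — and generates synthetic aligned sequences used as test
fixtures for the whole pipeline.

## Layout

| module | contents |
|---|---|
| `ktheta.alignment` | aligned FASTA I/O, pairwise distances (pairwise deletion), JC/K2P multiple-hit correction, distance-matrix TSV/PHYLIP output |
| `ktheta.diversity` | π, θ, zero-diversity conventions, molecular-clock utility |
| `ktheta.njtree` | deterministic neighbor joining, site-resampling bootstrap, support-based collapsing, midpoint/outgroup rooting, Newick-with-support I/O |
| `ktheta.delimit` | recursive K/θ delimitation (multiplier table 4.0/4.1/4.3, polytomy smallest-K rule), pairwise-difference histogram, lineages-through-time |
| `ktheta.coalescent` | TMRCA sampling, two-population genealogies with background lineages, reciprocal-monophyly probabilities, Jukes-Cantor sequence simulation |
| `ktheta.pipeline` | alignment → distances → supported tree → species partition, plus tabular writers |

## Command line

```bash
# delimit species in an aligned FASTA (NJ + 1000 bootstraps by default)
ktheta delimit alignment.fasta --support 0.70 --bootstrap 1000 \
    --model jc --root midpoint --seed 1 --out results/

# bring your own tree (support values as internal node labels)
ktheta delimit alignment.fasta --tree tree.nwk --out results/

# synthetic two-population fixture (FASTA + truth table + genealogy)
ktheta simulate --tau 8 --n1 5 --n2 5 --theta 0.01 --length 500 \
    --seed 1 --out fixtures/

# conditional probability that two populations are reciprocally
# monophyletic given that small samples from them are
ktheta rmprob --tau 4 --n1 2 --n2 2 --background 100 --reps 100000 --seed 1
```

`delimit` writes `partition.tsv` (tip → species), `decisions.tsv` (every
K/θ comparison with θ used, D, K, multiplier, ratio, verdict and flags),
`diversity.tsv`, `histogram.tsv` (1% bins, within/between split),
`tree.nwk` (species-annotated) and the D/K distance matrices.

## Conventions

* Time unit: Ne generations (pairwise coalescence rate 1), so θ = 2Neμ
  and τ = K/θ hold exactly; effectively haploid loci (organelle genes).
* Distances: uncorrected D for within-clade diversity and bootstrapping;
  model-corrected K (default JC) for between-clade divergence.
* Split decisions floor θ at the 95% upper bound consistent with zero
  observed diversity at the pooled sample size, preventing shallow or
  monomorphic clades from manufacturing split evidence.
* All stochastic operations take explicit seeds and are reproducible.
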