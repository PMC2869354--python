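"""Within-clade nucleotide diversity and theta (2*Ne*mu) estimation.

Diversity pi is the mean pairwise uncorrected difference d multiplied by the
sample-size correction n/(n-1); when the observed d is exactly zero the
minimum-resolvable convention is used instead: one pairwise difference is
1/L, giving pi = 2/(L*n*(n-1)).  Theta is pi/(1 - 4*pi/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .alignment import PairwiseDistanceMatrix

__all__ = [
    "CladeDiversity",
    "mean_pairwise_difference",
    "nucleotide_diversity",
    "theta_from_pi",
    "theta_zero_upper_bound",
    "clock_time",
    "clade_diversity",
]


@dataclass(frozen=True)
class CladeDiversity:
    """Sample size, mean difference, diversity and theta for one clade.

    For singleton clades (n == 1) pi and theta are NaN: the estimators are
    undefined and delimitation must rely on the sister clade.
    """

    tip_ids: frozenset[str]
    n: int
    d: float
    pi: float
    theta: float
    L: int

    @property
    def is_singleton(self) -> bool:
        return self.n == 1

    @property
    def has_theta(self) -> bool:
        return not math.isnan(self.theta)


def mean_pairwise_difference(
    matrix: PairwiseDistanceMatrix, tips: Iterable[str]
) -> float:
    """Mean uncorrected D over all unordered pairs within ``tips``."""
    tips = list(tips)
    if len(tips) < 2:
        raise ValueError("mean pairwise difference needs at least two tips")
    return matrix.mean_within(tips)


def nucleotide_diversity(d: float, n: int, L: int) -> float:
    """pi from mean pairwise difference d and sample size n.

    ``L`` is the (globally trimmed) alignment length, used only by the
    zero-difference fallback.
    """
    if n < 2:
        raise ValueError(f"nucleotide diversity undefined for n={n}")
    if L < 1:
        raise ValueError(f"invalid alignment length L={L}")
    if d < 0:
        raise ValueError(f"negative mean difference d={d}")
    if d == 0.0:
        return 2.0 / (L * n * (n - 1))
    return d * n / (n - 1)


def theta_zero_upper_bound(n: int, L: int, confidence: float = 0.95) -> float:
    """Largest theta consistent with zero observed diversity in a clade.

    Under the Kingman coalescent the number of segregating sites among n
    sequences, given total tree length T, is Poisson(theta*L*T/2), and the
    epoch decomposition gives P(S = 0) = prod_{k=2..n} (1 + theta*L/(k-1))^-1.
    This solves P(S = 0) = 1 - confidence for theta: an exact one-sided
    upper confidence bound used by split decisions in place of the
    reporting fallback pi = 2/(L*n*(n-1)), which shrinks with n and badly
    understates theta for clades that merely happen to be monomorphic.
    """
    if n < 2:
        raise ValueError("upper bound needs n >= 2")
    if L < 1:
        raise ValueError(f"invalid alignment length L={L}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    target = -math.log(1.0 - confidence)

    def log_p0_deficit(x: float) -> float:  # x = theta * L
        return sum(math.log1p(x / (k - 1)) for k in range(2, n + 1)) - target

    if n == 2:
        x = 1.0 / (1.0 - confidence) - 1.0
    else:
        from scipy.optimize import brentq

        x = brentq(log_p0_deficit, 1e-12, 1.0 / (1.0 - confidence))
    return x / L


def theta_from_pi(pi: float) -> float:
    """theta = pi / (1 - 4*pi/3); requires 0 <= pi < 0.75."""
    if not 0.0 <= pi < 0.75:
        raise ValueError(f"pi={pi} outside [0, 0.75)")
    return pi / (1.0 - 4.0 * pi / 3.0)


def clock_time(K: float, rate: float = 0.022) -> float:
    """Divergence time in My from corrected distance K and a clock rate.

    Default rate is the cox1 clock of 2.2% per My (0.022/My).
    """
    if rate <= 0:
        raise ValueError(f"clock rate must be positive, got {rate}")
    if K < 0:
        raise ValueError(f"negative distance {K}")
    return K / rate


def clade_diversity(
    matrix: PairwiseDistanceMatrix, tips: Iterable[str], L: int | None = None
) -> CladeDiversity:
    """Assemble a CladeDiversity for a tip set from a distance matrix."""
    tips = frozenset(tips)
    L = matrix.L if L is None else L
    n = len(tips)
    if n == 0:
        raise ValueError("empty clade")
    if n == 1:
        return CladeDiversity(tips, 1, 0.0, math.nan, math.nan, L)
    d = mean_pairwise_difference(matrix, tips)
    pi = nucleotide_diversity(d, n, L)
    # beyond the estimator's domain theta diverges; +inf keeps downstream
    # ratio tests conservative (saturated clades can only absorb, not split)
    theta = theta_from_pi(pi) if pi < 0.75 else math.inf
    return CladeDiversity(tips, n, d, pi, theta, L)


def write_diversity_tsv(path, clades: dict[str, CladeDiversity]) -> None:
    """Per-clade diversity table: clade_id, n, d, pi, theta, L."""
    with open(path, "w") as fh:
        fh.write("clade_id\tn\td\tpi\ttheta\tL\n")
        for label, cd in clades.items():
            pi = "NA" if math.isnan(cd.pi) else repr(cd.pi)
            theta = "NA" if math.isnan(cd.theta) else repr(cd.theta)
            fh.write(f"{label}\t{cd.n}\t{cd.d!r}\t{pi}\t{theta}\t{cd.L}\n")
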