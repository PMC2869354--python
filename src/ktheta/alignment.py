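"""Aligned-sequence containers, FASTA I/O and pairwise distances.

Distances come in two flavours throughout the package: ``D`` is the raw
(uncorrected) fraction of differing sites among sites comparable in a pair,
and ``K`` is ``D`` corrected for multiple substitutions under a chosen model
(``none``, Jukes-Cantor or Kimura two-parameter).  Sites containing a gap or
``N`` in either member of a pair are excluded for that pair only (pairwise
deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, NoComparableSitesError, SaturationError

__all__ = [
    "AlignedSequenceSet",
    "PairwiseDistanceMatrix",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "p_distance",
    "correct_distance",
    "distance_matrix",
]

_ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_MISSING = 255

# purines (A, G) encode 0 and 2; pyrimidines (C, T) encode 1 and 3, so a
# substitution is a transition iff the two codes share parity
_PURINE_PARITY = 0


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An alignment: identified, equal-length nucleotide sequences."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no sequences")
        length = len(self.records[0][1])
        if length < 1:
            raise AlignmentError(
                f"sequence {self.records[0][0]!r} is empty"
            )
        seen: set[str] = set()
        for rid, seq in self.records:
            if not rid:
                raise AlignmentError("empty sequence identifier")
            if rid in seen:
                raise AlignmentError(f"duplicate sequence identifier {rid!r}")
            seen.add(rid)
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence {rid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - set("ACGTN-")
            if bad:
                raise AlignmentError(
                    f"sequence {rid!r} contains unsupported symbols {sorted(bad)}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AlignedSequenceSet":
        return cls(tuple((rid, seq.upper()) for rid, seq in pairs))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix; A,C,G,T -> 0..3, gap/N -> 255."""
        out = np.full((self.n, self.length), _MISSING, dtype=np.uint8)
        table = np.full(256, _MISSING, dtype=np.uint8)
        for c, i in _CODE.items():
            table[ord(c)] = i
        for row, (_, seq) in enumerate(self.records):
            out[row] = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        return out

    def subset(self, ids: Sequence[str]) -> "AlignedSequenceSet":
        want = set(ids)
        return AlignedSequenceSet(
            tuple((r, s) for r, s in self.records if r in want)
        )

    def resample_sites(self, site_indices: np.ndarray) -> "AlignedSequenceSet":
        """Bootstrap helper: new alignment from the given site columns."""
        return AlignedSequenceSet(
            tuple(
                (rid, "".join(seq[i] for i in site_indices))
                for rid, seq in self.records
            )
        )


def read_aligned_fasta(path: str | Path) -> AlignedSequenceSet:
    """Read a multi-FASTA alignment; residues are uppercased on input."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return AlignedSequenceSet(tuple(records))


def write_aligned_fasta(aln: AlignedSequenceSet, path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records),
        str(path),
        "fasta",
    )


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected distance between two aligned sequences.

    Returns ``(D, comparable_sites)`` under pairwise deletion of sites where
    either sequence has a gap or ``N``.
    """
    if len(a) != len(b):
        raise AlignmentError("sequences differ in length")
    comparable = 0
    diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _ALPHABET and y in _ALPHABET:
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        raise NoComparableSitesError("no comparable sites in pair")
    return diffs / comparable, comparable


def correct_distance(
    D: float,
    model: str = "JC",
    transition_fraction: float | None = None,
) -> float:
    """Correct an observed distance ``D`` for multiple hits.

    ``model`` is one of ``"none"``, ``"JC"``, ``"K2P"``.  For K2P the
    observed differences are split into transitions and transversions using
    ``transition_fraction`` (default 0.5).
    """
    if D < 0:
        raise ValueError(f"negative distance {D}")
    model = model.upper() if model.lower() != "none" else "none"
    if model == "none":
        return D
    if model == "JC":
        if D >= 0.75:
            raise SaturationError(
                f"D={D} at or beyond Jukes-Cantor saturation (0.75)"
            )
        # max() guards the K >= D invariant against 1-ulp rounding at tiny D
        return max(D, -0.75 * math.log1p(-4.0 * D / 3.0))
    if model == "K2P":
        f = 0.5 if transition_fraction is None else transition_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError("transition_fraction must lie in [0, 1]")
        P = f * D
        Q = (1.0 - f) * D
        x = 1.0 - 2.0 * P - Q
        y = 1.0 - 2.0 * Q
        if x <= 0.0 or y <= 0.0:
            raise SaturationError(f"D={D} beyond K2P saturation for P={P}, Q={Q}")
        return max(D, -0.5 * math.log(x) - 0.25 * math.log(y))
    raise ValueError(f"unknown correction model {model!r}")


@dataclass
class PairwiseDistanceMatrix:
    """Symmetric per-site distance matrices over a fixed tip order.

    ``D`` holds uncorrected distances, ``K`` corrected ones (``K >= D``
    element-wise), ``comparable_sites`` the pairwise-deletion site counts.
    """

    ids: tuple[str, ...]
    D: np.ndarray
    K: np.ndarray
    comparable_sites: np.ndarray
    L: int
    model: str = "JC"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name, m in (("D", self.D), ("K", self.K)):
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix shape {m.shape} != ({n}, {n})")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} matrix is not symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} matrix has non-zero diagonal")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, rid: str) -> int:
        return self._index[rid]

    def pair(self, a: str, b: str) -> tuple[float, float]:
        """(D, K) for a pair of tip ids."""
        i, j = self._index[a], self._index[b]
        return float(self.D[i, j]), float(self.K[i, j])

    def mean_cross(self, tips_a: Iterable[str], tips_b: Iterable[str]) -> tuple[float, float]:
        """Mean (D, K) over all pairs with one tip in each set."""
        ia = [self._index[t] for t in tips_a]
        ib = [self._index[t] for t in tips_b]
        if not ia or not ib:
            raise ValueError("empty tip set")
        sub_d = self.D[np.ix_(ia, ib)]
        sub_k = self.K[np.ix_(ia, ib)]
        return float(sub_d.mean()), float(sub_k.mean())

    def mean_within(self, tips: Iterable[str]) -> float:
        """Mean uncorrected D over all unordered pairs within a tip set."""
        idx = [self._index[t] for t in tips]
        if len(idx) < 2:
            raise ValueError("need at least two tips for within-clade mean")
        sub = self.D[np.ix_(idx, idx)]
        m = len(idx)
        return float(sub[np.triu_indices(m, k=1)].mean())

    def condensed(self, use: str = "D") -> np.ndarray:
        m = self.D if use == "D" else self.K
        return m[np.triu_indices(self.n, k=1)]

    # --- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path, use: str = "D") -> None:
        m = self.D if use == "D" else self.K
        with open(path, "w") as fh:
            fh.write("\t".join(("id", *self.ids)) + "\n")
            for i, rid in enumerate(self.ids):
                fh.write(
                    rid + "\t" + "\t".join(repr(float(v)) for v in m[i]) + "\n"
                )

    @classmethod
    def from_tsv(
        cls, path: str | Path, L: int, model: str = "none"
    ) -> "PairwiseDistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in parts[1:]])
        D = np.asarray(rows, dtype=float)
        comparable = np.full(D.shape, L, dtype=int)
        return cls(tuple(header), D, D.copy(), comparable, L=L, model=model)

    def to_phylip(self, path: str | Path, use: str = "D") -> None:
        m = self.D if use == "D" else self.K
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, rid in enumerate(self.ids):
                fh.write(
                    f"{rid:<10s} " + " ".join(f"{v:.8f}" for v in m[i]) + "\n"
                )


def _pair_counts(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair (diff, transition, comparable) counts for an encoded alignment."""
    n = enc.shape[0]
    diffs = np.zeros((n, n), dtype=np.int64)
    transitions = np.zeros((n, n), dtype=np.int64)
    comparable = np.zeros((n, n), dtype=np.int64)
    valid = enc != _MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            c = int(both.sum())
            a = enc[i, both]
            b = enc[j, both]
            ne = a != b
            d = int(ne.sum())
            # transition iff both purine (codes 0,2) or both pyrimidine (1,3)
            ts = int((ne & ((a & 1) == (b & 1))).sum())
            comparable[i, j] = comparable[j, i] = c
            diffs[i, j] = diffs[j, i] = d
            transitions[i, j] = transitions[j, i] = ts
    return diffs, transitions, comparable


def distance_matrix(
    aln: AlignedSequenceSet, model: str = "JC"
) -> PairwiseDistanceMatrix:
    """Compute all pairwise D and model-corrected K for an alignment.

    Raises with the offending pair named if any pair has no comparable
    sites or is saturated under the chosen model.
    """
    if aln.n < 2:
        raise AlignmentError("need at least two sequences")
    enc = aln.encoded()
    diffs, transitions, comparable = _pair_counts(enc)
    n = aln.n
    D = np.zeros((n, n), dtype=float)
    K = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            c = comparable[i, j]
            if c == 0:
                raise NoComparableSitesError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            d = diffs[i, j] / c
            tf = transitions[i, j] / diffs[i, j] if diffs[i, j] else None
            try:
                k = correct_distance(d, model=model, transition_fraction=tf)
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}): {exc}"
                ) from exc
            D[i, j] = D[j, i] = d
            K[i, j] = K[j, i] = k
    return PairwiseDistanceMatrix(
        aln.ids, D, K, comparable, L=aln.length, model=model
    )
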