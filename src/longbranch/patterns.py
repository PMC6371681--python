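"""Jukes-Cantor site-pattern classes, probabilities and log-likelihoods.

Under the Jukes-Cantor (JC) model all four bases are exchangeable, so the
4^k site patterns of a k-taxon alignment collapse into equivalence classes
determined only by which taxa share a base.  For three taxa there are five
classes, ``xxx, xxy, xyx, yxx, xyz`` (multiplicities 4, 12, 12, 12, 24);
for four taxa there are fifteen, one per set partition of the taxa, with
multiplicities summing to 256.  Class counts are the sufficient statistics
for all branch-length inference in this package.

Log-likelihoods are reported per *specific* site pattern (class probability
divided by class multiplicity), the scale on which the boundary optima have
the closed-form values -n log 4, -n log 16 and -n log 64.  The multiplicity
term is an additive constant and does not affect any maximization.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "INF",
    "PatternCounts3",
    "PatternCounts4",
    "BranchLengths3",
    "CLASS_NAMES_3",
    "CLASS_MULT_3",
    "CLASS_NAMES_4",
    "CLASS_MULT_4",
    "jc_same_prob",
    "jc_diff_prob",
    "pattern_class_probs_3",
    "log_likelihood_3",
    "count_patterns",
    "read_alignment",
]

#: Explicit representation of an infinite branch length (saturation).
INF = math.inf

CLASS_NAMES_3 = ("xxx", "xxy", "xyx", "yxx", "xyz")
CLASS_MULT_3 = np.array([4, 12, 12, 12, 24])

_BASES = "ACGT"


def _pattern_class(bases: Sequence[str]) -> str:
    """Canonical class label of a site pattern: first occurrence -> x, y, z, w."""
    letters = "xyzw"
    seen: dict[str, str] = {}
    out = []
    for b in bases:
        if b not in seen:
            seen[b] = letters[len(seen)]
        out.append(seen[b])
    return "".join(out)


def _enumerate_classes(k: int) -> tuple[tuple[str, ...], np.ndarray]:
    """Enumerate pattern classes of k taxa from the 4**k patterns.

    Returns class labels (lexicographic) and their multiplicities; the orbit
    construction guarantees multiplicities sum to 4**k.
    """
    mult: dict[str, int] = {}
    for pat in itertools.product(_BASES, repeat=k):
        mult[_pattern_class(pat)] = mult.get(_pattern_class(pat), 0) + 1
    labels = tuple(sorted(mult))
    return labels, np.array([mult[c] for c in labels])


CLASS_NAMES_4, CLASS_MULT_4 = _enumerate_classes(4)
assert int(CLASS_MULT_4.sum()) == 256 and len(CLASS_NAMES_4) == 15


@dataclass(frozen=True)
class PatternCounts3:
    """Counts of the five JC pattern classes of a three-taxon alignment.

    Classes are defined relative to the taxon order (A, B, C): ``xxy`` means
    A and B agree and C differs, ``xyx`` means A and C agree, ``yxx`` means
    B and C agree, ``xyz`` means all three differ.
    """

    n_xxx: int
    n_xxy: int
    n_xyx: int
    n_yxx: int
    n_xyz: int

    def __post_init__(self):
        for name, v in zip(CLASS_NAMES_3, self.as_array()):
            if v < 0:
                raise ValueError(f"negative count n_{name}={v}")

    @property
    def n(self) -> int:
        return int(self.as_array().sum())

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.n_xxx, self.n_xxy, self.n_xyx, self.n_yxx, self.n_xyz]
        )

    @classmethod
    def from_array(cls, arr: Iterable[int]) -> "PatternCounts3":
        a = [int(v) for v in arr]
        if len(a) != 5:
            raise ValueError("expected 5 class counts")
        return cls(*a)

    def to_json(self) -> str:
        return json.dumps({f"n_{c}": int(v) for c, v in zip(CLASS_NAMES_3, self.as_array())})

    @classmethod
    def from_json(cls, s: str) -> "PatternCounts3":
        d = json.loads(s)
        return cls(*(int(d[f"n_{c}"]) for c in CLASS_NAMES_3))


@dataclass(frozen=True)
class PatternCounts4:
    """Counts over the 15 JC pattern classes of a four-taxon alignment.

    Classes are keyed by canonical labels over the taxon order (W, X, Y, Z),
    e.g. ``xxyy`` = W,X share one base and Y,Z share another.
    """

    counts: tuple

    def __post_init__(self):
        c = tuple(int(v) for v in self.counts)
        if len(c) != 15:
            raise ValueError("expected 15 class counts")
        if any(v < 0 for v in c):
            raise ValueError("negative pattern count")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.array(self.counts)

    @classmethod
    def from_dict(cls, d: dict) -> "PatternCounts4":
        return cls(tuple(int(d.get(c, 0)) for c in CLASS_NAMES_4))

    def to_dict(self) -> dict:
        return {c: int(v) for c, v in zip(CLASS_NAMES_4, self.counts)}


@dataclass(frozen=True)
class BranchLengths3:
    """Branch lengths (d_A, d_B, d_C) in expected substitutions per site.

    Infinite lengths are explicit (``math.inf``); probabilities then use the
    stationary limit exactly.
    """

    d_A: float
    d_B: float
    d_C: float

    def __post_init__(self):
        for d in self.as_tuple():
            if not (d >= 0):  # also rejects NaN
                raise ValueError(f"branch length must be >= 0, got {d}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d_A, self.d_B, self.d_C)


def jc_same_prob(d):
    """Probability the two ends of a branch of length ``d`` carry the same base.

    The JC closed form 1/4 + (3/4) exp(-4d/3); 1 at d=0 and 1/4 at d=inf.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(np.isnan(d)):
        raise ValueError("branch length must be in [0, inf]")
    out = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
    return float(out) if out.ndim == 0 else out


def jc_diff_prob(d):
    """Probability of observing one *specific* different base across a branch."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(np.isnan(d)):
        raise ValueError("branch length must be in [0, inf]")
    out = 0.25 - 0.25 * np.exp(-4.0 * d / 3.0)
    return float(out) if out.ndim == 0 else out


def _class_probs_3_from_e(eA, eB, eC):
    """Per-specific-pattern probabilities of the 5 classes from e = exp(-4d/3).

    Obtained by summing the internal-node state out of the product of JC
    transition probabilities; each probability is multilinear in (eA, eB, eC).
    Returns an array broadcast over the inputs with last axis = class.
    """
    eA, eB, eC = np.broadcast_arrays(
        np.asarray(eA, float), np.asarray(eB, float), np.asarray(eC, float)
    )
    s = [(1 + 3 * e) / 4 for e in (eA, eB, eC)]
    t = [(1 - e) / 4 for e in (eA, eB, eC)]
    sA, sB, sC = s
    tA, tB, tC = t
    p = np.stack(
        [
            0.25 * (sA * sB * sC + 3 * tA * tB * tC),
            0.25 * (sA * sB * tC + tA * tB * sC + 2 * tA * tB * tC),
            0.25 * (sA * tB * sC + tA * sB * tC + 2 * tA * tB * tC),
            0.25 * (tA * sB * sC + sA * tB * tC + 2 * tA * tB * tC),
            0.25 * (sA * tB * tC + tA * sB * tC + tA * tB * sC + tA * tB * tC),
        ],
        axis=-1,
    )
    return p


def _branch_to_e(d: float) -> float:
    return 0.0 if math.isinf(d) else math.exp(-4.0 * d / 3.0)


def pattern_class_probs_3(branches: BranchLengths3) -> np.ndarray:
    """Probabilities of the five pattern classes on a three-taxon tree.

    Aggregated over the nucleotide assignments within each class
    (multiplicities 4, 12, 12, 12, 24); sums to 1.
    """
    if not isinstance(branches, BranchLengths3):
        branches = BranchLengths3(*branches)
    e = [_branch_to_e(d) for d in branches.as_tuple()]
    p = _class_probs_3_from_e(*e) * CLASS_MULT_3
    return p


def log_likelihood_3(counts: PatternCounts3, branches) -> float:
    """Log-likelihood of three-taxon class counts at given branch lengths.

    Per-specific-pattern scale: sum_r n_r log(P_class_r / multiplicity_r),
    in natural log; -inf when an observed class has probability zero.
    """
    if not isinstance(branches, BranchLengths3):
        branches = BranchLengths3(*branches)
    n_r = counts.as_array().astype(float)
    e = [_branch_to_e(d) for d in branches.as_tuple()]
    p = _class_probs_3_from_e(*e)  # already per specific pattern
    ll = 0.0
    for nr, pr in zip(n_r, p):
        if nr == 0:
            continue
        if pr <= 0.0:
            return -math.inf
        ll += nr * math.log(pr)
    return ll


def _validate_alignment(seqs: Sequence[str]) -> list[str]:
    seqs = [str(s).upper() for s in seqs]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    ok = set(_BASES)
    for s in seqs:
        bad = set(s) - ok
        if bad:
            raise ValueError(f"non-ACGT symbols in alignment: {sorted(bad)}")
    return seqs


def count_patterns(seqs: Sequence[str]):
    """Reduce an ungapped 3- or 4-taxon alignment to pattern-class counts.

    ``seqs`` is a list of equal-length nucleotide strings in taxon order
    (A, B, C) or (W, X, Y, Z).  Site order is irrelevant.
    """
    seqs = _validate_alignment(seqs)
    k = len(seqs)
    if k == 3:
        # canonical first-occurrence labels -> conventional class names
        # ("xyy" is the canonical string of the yxx class, B = C != A)
        idx = {"xxx": 0, "xxy": 1, "xyx": 2, "xyy": 3, "xyz": 4}
        tally3 = [0] * 5
        for col in zip(*seqs):
            tally3[idx[_pattern_class(col)]] += 1
        return PatternCounts3(*tally3)
    if k != 4:
        raise ValueError("expected 3 or 4 sequences")
    idx4 = {c: i for i, c in enumerate(CLASS_NAMES_4)}
    tally = [0] * 15
    for col in zip(*seqs):
        tally[idx4[_pattern_class(col)]] += 1
    return PatternCounts4(tuple(tally))


def read_alignment(path, fmt: str = "fasta"):
    """Read a 3- or 4-sequence alignment (FASTA or sequential PHYLIP).

    Returns (names, sequences); pass the sequences to :func:`count_patterns`.
    """
    from Bio import SeqIO

    fmt = {"fasta": "fasta", "phylip": "phylip-sequential"}.get(fmt, fmt)
    records = list(SeqIO.parse(str(path), fmt))
    if len(records) not in (3, 4):
        raise ValueError(f"expected 3 or 4 sequences, found {len(records)}")
    return [r.id for r in records], [str(r.seq) for r in records]
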