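"""Pairwise JC distances and distance-matrix predictors of ML anomalies.

On an unrooted three-taxon tree the three pairwise distances fit the three
branches exactly (the three-point formulas), so minimum evolution,
neighbor-joining and least squares all coincide.  A violated triangle
inequality forces a non-positive fitted branch; saturation (mismatch
fraction >= 3/4) forces an infinite distance.  These conditions predict,
with measured accuracy, when the ML tree will carry a zero or infinite
branch length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .patterns import INF, PatternCounts3

__all__ = [
    "DistanceTriple",
    "AnomalyPrediction",
    "mismatch_fractions",
    "jc_distance",
    "dm_branch_lengths",
    "predict_anomalies",
]


def mismatch_fractions(counts: PatternCounts3) -> tuple[float, float, float]:
    """Fractions of mismatching sites (U_AB, U_AC, U_BC) from class counts.

    U_AB = (n_xyz + n_xyx + n_yxx)/n and cyclic analogues: a pair mismatches
    in every class where its two taxa carry different letters.
    """
    n = counts.n
    if n == 0:
        raise ValueError("cannot compute mismatch fractions with n = 0 sites")
    u_ab = (counts.n_xyz + counts.n_xyx + counts.n_yxx) / n
    u_ac = (counts.n_xxy + counts.n_yxx + counts.n_xyz) / n
    u_bc = (counts.n_xxy + counts.n_xyx + counts.n_xyz) / n
    return (u_ab, u_ac, u_bc)


def jc_distance(U: float) -> float:
    """JC distance -(3/4) ln(1 - 4U/3) from a mismatch fraction U.

    Infinite at and beyond saturation (U >= 0.75).
    """
    if not (0.0 <= U <= 1.0):
        raise ValueError(f"mismatch fraction must be in [0, 1], got {U}")
    if U >= 0.75:
        return INF
    return -0.75 * math.log1p(-4.0 * U / 3.0)


@dataclass(frozen=True)
class DistanceTriple:
    """Pairwise JC distances of a three-taxon alignment, with the mismatch
    fractions they were derived from.  D_ij is infinite iff U_ij >= 3/4."""

    D_AB: float
    D_AC: float
    D_BC: float
    U_AB: float = field(default=math.nan)
    U_AC: float = field(default=math.nan)
    U_BC: float = field(default=math.nan)

    def __post_init__(self):
        for d in (self.D_AB, self.D_AC, self.D_BC):
            if not (d >= 0):
                raise ValueError(f"distance must be >= 0, got {d}")

    @classmethod
    def from_counts(cls, counts: PatternCounts3) -> "DistanceTriple":
        u = mismatch_fractions(counts)
        return cls(*(jc_distance(x) for x in u), *u)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.D_AB, self.D_AC, self.D_BC)


def dm_branch_lengths(D: DistanceTriple) -> tuple[float, float, float]:
    """Exact three-point fit of pairwise distances to branch lengths.

    d_A = (D_AB + D_AC - D_BC)/2 and cyclic analogues.  Outputs may be
    negative (violated triangle inequality) and that is meaningful here.
    With exactly one infinite distance the fit gives one -inf branch and two
    +inf branches, matching the interpretation of an unplaceable taxon.
    """
    dab, dac, dbc = D.as_tuple()

    def half_sum(p, q, r):
        # (p + q - r)/2 with explicit infinity semantics: inf - inf on the
        # same side cannot occur for JC distances derived from one dataset
        # in the combinations used here except the all/two-infinite cases,
        # where the symmetric answer is +inf.
        if math.isinf(p) and math.isinf(r) or math.isinf(q) and math.isinf(r):
            return INF
        return (p + q - r) / 2.0

    d_a = half_sum(dab, dac, dbc)
    d_b = half_sum(dab, dbc, dac)
    d_c = half_sum(dac, dbc, dab)
    return (d_a, d_b, d_c)


@dataclass(frozen=True)
class AnomalyPrediction:
    """Predicted zero / infinite branches of the ML tree from distances.

    ``zero`` and ``infinite`` are frozensets over {"A", "B", "C"};
    ``at_least_two_infinite`` marks the fully saturated case where only
    "at least two branches are infinite" can be asserted.
    """

    zero: frozenset
    infinite: frozenset
    at_least_two_infinite: bool = False

    def __post_init__(self):
        if self.zero & self.infinite:
            raise ValueError("a branch cannot be predicted both zero and infinite")

    @property
    def any_zero(self) -> bool:
        return bool(self.zero)

    @property
    def any_infinite(self) -> bool:
        return bool(self.infinite) or self.at_least_two_infinite


def predict_anomalies(D: DistanceTriple) -> AnomalyPrediction:
    """Predict zero / infinite ML branch lengths from a distance triple.

    Decision list, infinite rows first:

    * all three distances infinite -> at least two branches infinite;
    * D_iY = D_iZ = inf for taxon i's two distances -> d_i infinite
      (no information about where i attaches);
    * D_jk >= D_ij + D_ik (including D_jk = inf) -> d_i = 0, from the
      violated triangle inequality in the exact three-point fit.
    """
    dab, dac, dbc = D.as_tuple()
    inf_ab, inf_ac, inf_bc = (math.isinf(x) for x in (dab, dac, dbc))
    n_inf = inf_ab + inf_ac + inf_bc

    if n_inf == 3:
        return AnomalyPrediction(frozenset(), frozenset(), at_least_two_infinite=True)
    if n_inf == 2:
        infinite = set()
        if inf_ab and inf_ac:
            infinite.add("A")
        if inf_ab and inf_bc:
            infinite.add("B")
        if inf_ac and inf_bc:
            infinite.add("C")
        return AnomalyPrediction(frozenset(), frozenset(infinite))

    zero = set()
    if dbc >= dab + dac:  # includes dbc = inf with the others finite
        zero.add("A")
    if dac >= dab + dbc:
        zero.add("B")
    if dab >= dac + dbc:
        zero.add("C")
    return AnomalyPrediction(frozenset(zero), frozenset())
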