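"""Four-taxon (quartet) ML fitting and long-branch topology classification.

Taxa are ordered (W, X, Y, Z).  The generating tree of the two-long-branch
experiments has W and X at the ends of a path of fixed length with the long
branches to Y and Z attached along it, Y nearer W: the true unrooted
topology is WY|XZ.  A quartet fit optimizes the five branch lengths of each
of the three resolved topologies and takes the best; the winner is
classified into four outcomes:

* ``c`` -- correct topology WY|XZ, resolved (internal branch > 0);
* ``e`` -- swapped topology WZ|XY, resolved;
* ``d`` -- long branches joined, WX|YZ, resolved;
* ``f`` -- star: the winning tree's internal branch is exactly 0, so all
  three resolved topologies coincide.

For each outcome the attachment points of Y and Z are expressed as
fractions along the W-X path; their separation ``y`` (signed: positive when
Z is nearer X, as in the true tree) is 0 for outcomes ``d`` and ``f``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .ml import _ascend, L_CAP, _E_LO
from .patterns import (
    CLASS_MULT_4,
    CLASS_NAMES_4,
    PatternCounts4,
    _pattern_class,
)

__all__ = [
    "TOPOLOGIES",
    "QuartetResult",
    "QuartetFit",
    "QuartetML",
    "fit_quartet",
    "batched_fit_quartet",
    "quartet_class_probs",
    "log_likelihood_4",
    "newick_3",
    "newick_quartet",
]

#: The three resolved unrooted quartet topologies, named by their split.
#: Branch order within a topology: (b_W, b_X, b_Y, b_Z, b_internal).
TOPOLOGIES = ("WY|XZ", "WX|YZ", "WZ|XY")

#: Tip pairs attached to the two internal nodes (u, v) per topology,
#: as indices into the taxon order (W, X, Y, Z).
_NODE_TIPS = {
    "WY|XZ": ((0, 2), (1, 3)),
    "WX|YZ": ((0, 1), (2, 3)),
    "WZ|XY": ((0, 3), (1, 2)),
}

_BASES = "ACGT"

# One representative site pattern (base indices for W, X, Y, Z) per class.
_REPS = {}
for _pat in itertools.product(range(4), repeat=4):
    _cls = _pattern_class([_BASES[i] for i in _pat])
    _REPS.setdefault(_cls, _pat)
_REP_IDX = np.array([_REPS[c] for c in CLASS_NAMES_4])  # (15, 4)


def _trans(e):
    """JC transition matrices from e = exp(-4d/3); e is (R,) -> (R, 4, 4)."""
    e = np.asarray(e, float)
    eye = np.eye(4)
    return e[:, None, None] * eye + ((1 - e) / 4)[:, None, None]


def quartet_class_probs(topology: str, e_cols) -> np.ndarray:
    """Per-specific-pattern probabilities of the 15 classes, batched.

    ``e_cols`` is a sequence of five (R,) arrays, e = exp(-4d/3) for
    (b_W, b_X, b_Y, b_Z, b_internal).  The two internal node states are
    summed out; each probability is multilinear in the five e's.
    """
    if topology not in _NODE_TIPS:
        raise ValueError(f"unknown topology {topology!r}; one of {TOPOLOGIES}")
    (u1, u2), (v1, v2) = _NODE_TIPS[topology]
    eW, eX, eY, eZ, eI = (np.asarray(c, float) for c in e_cols)
    tips = {0: _trans(eW), 1: _trans(eX), 2: _trans(eY), 3: _trans(eZ)}
    TI = _trans(eI)
    # gather tip transition columns at each class representative's base
    bu1 = _REP_IDX[:, u1]
    bu2 = _REP_IDX[:, u2]
    bv1 = _REP_IDX[:, v1]
    bv2 = _REP_IDX[:, v2]
    M1 = tips[u1][:, :, bu1] * tips[u2][:, :, bu2]  # (R, 4, 15)
    M2 = tips[v1][:, :, bv1] * tips[v2][:, :, bv2]
    p = 0.25 * np.einsum("ruc,ruv,rvc->rc", M1, TI, M2, optimize=True)
    return p


def log_likelihood_4(counts: PatternCounts4, topology: str, lengths) -> float:
    """Exact log-likelihood of 15-class counts on a resolved quartet.

    ``lengths`` is (b_W, b_X, b_Y, b_Z, b_internal), each in [0, inf];
    per-specific-pattern scale, natural log.
    """
    lengths = [float(d) for d in lengths]
    if len(lengths) != 5 or any(not (d >= 0) for d in lengths):
        raise ValueError("expected 5 branch lengths in [0, inf]")
    e = [np.array([0.0 if math.isinf(d) else math.exp(-4 * d / 3)]) for d in lengths]
    p = quartet_class_probs(topology, e)[0]
    nr = counts.as_array()
    ll = 0.0
    for n_r, p_r in zip(nr, p):
        if n_r == 0:
            continue
        if p_r <= 0:
            return -math.inf
        ll += n_r * math.log(p_r)
    return ll


@dataclass(frozen=True)
class QuartetResult:
    """Per-topology ML fit: branch lengths (b_W, b_X, b_Y, b_Z, b_int)."""

    topology: str
    branch_lengths: tuple
    loglik: float


@dataclass(frozen=True)
class QuartetFit:
    """Best quartet over the three resolved topologies.

    ``label`` is the Fig-8-style outcome (c/d/e/f); ``y_frac`` and
    ``z_frac`` are the attachment fractions of Y and Z along the W-X path;
    ``y_sep`` their signed separation (0 for d and f).
    """

    per_topology: tuple
    winner: QuartetResult
    label: str
    y_frac: float
    z_frac: float
    y_sep: float
    tie: bool = False
    restarts: int = 0

    def summary(self) -> str:
        lines = ["Quartet ML fit", "=" * 40]
        for r in self.per_topology:
            mark = " *" if r.topology == self.winner.topology else ""
            bl = ", ".join(f"{d:.4g}" for d in r.branch_lengths)
            lines.append(f"{r.topology}  logL={r.loglik:.4f}  ({bl}){mark}")
        lines.append(f"outcome: {self.label}" + ("  (tie)" if self.tie else ""))
        lines.append(
            f"Y at {self.y_frac:.4f}, Z at {self.z_frac:.4f} on the W-X path"
            f" (separation {self.y_sep:+.4f})"
        )
        return "\n".join(lines)


def _positions(topology: str, bl) -> tuple[float, float, float]:
    """(y_frac, z_frac, y_sep) along the W-X path for a fitted topology."""
    bw, bx, by, bz, bi = bl
    if topology == "WY|XZ":
        path = bw + bi + bx
        if path == 0:
            return (math.nan, math.nan, 0.0)
        return (bw / path, (bw + bi) / path, bi / path)
    if topology == "WZ|XY":
        path = bw + bi + bx
        if path == 0:
            return (math.nan, math.nan, 0.0)
        return ((bw + bi) / path, bw / path, -bi / path)
    # WX|YZ: the Y,Z pair hangs off the path at the W-side internal node
    path = bw + bx
    if path == 0:
        return (math.nan, math.nan, 0.0)
    return (bw / path, bw / path, 0.0)


_TIE_TOL = 1e-9


def _classify(topology: str, bl) -> str:
    if bl[4] == 0.0:
        return "f"
    return {"WY|XZ": "c", "WX|YZ": "d", "WZ|XY": "e"}[topology]


def batched_fit_quartet(
    counts: np.ndarray, restarts: int = 5, seed: int | None = None, tol: float = 1e-9
):
    """Multi-start ML fit of all three topologies for a batch of quartets.

    Parameters
    ----------
    counts : (R, 15) array of class counts in the order of CLASS_NAMES_4.

    Returns
    -------
    dict with per-topology ``lengths`` (3, R, 5) and ``loglik`` (3, R),
    winner index (R,), labels (R,) in {c, d, e, f}, attachment fractions
    and separations, and tie flags.
    """
    nr = np.atleast_2d(np.asarray(counts, float))
    if nr.shape[1] != 15 or (nr < 0).any():
        raise ValueError("counts must be a (R, 15) array of non-negative counts")
    R = nr.shape[0]
    rng = np.random.default_rng(seed)
    # starting points: shared 5-branch analogue of the 3-taxon protocol
    # Deterministic battery first: near-star, long-tips, and the
    # "collapsed long tip, long internal branch" shapes that are local
    # optima when the long branches approach saturation.  Random
    # log-uniform restarts follow (the multi-start protocol).
    starts = [
        np.full(5, 0.1),
        np.array([0.1, 0.1, 2.0, 2.0, 0.1]),
        np.array([0.1, 0.1, 5.0, 5.0, 2.0]),
        np.array([0.1, 0.1, 3.0, 0.01, 3.0]),
        np.array([0.1, 0.1, 0.01, 3.0, 3.0]),
    ]
    for _ in range(max(1, restarts) - 1):
        d0 = np.exp(rng.uniform(math.log(1e-3), math.log(10.0), 5))
        starts.append(d0)
        # Y<->Z mirror, so the start set carries no systematic preference
        # between the two long-branch tips (swapped-topology outcomes must
        # be exchangeable when the long branches are saturated)
        starts.append(d0[[0, 1, 3, 2, 4]])
    all_lengths = np.empty((3, R, 5))
    all_ll = np.empty((3, R))
    for ti, topo in enumerate(TOPOLOGIES):
        probs_fn = lambda cols, t=topo: quartet_class_probs(t, cols)
        best_e, best_ll = None, np.full(R, -np.inf)
        for d0 in starts:
            e0 = np.exp(-4.0 * np.asarray(d0) / 3.0)
            e, ll = _ascend(nr, e0, probs_fn, tol=tol)
            if best_e is None:
                best_e, best_ll = e, ll
            else:
                b = ll > best_ll
                best_e[b] = e[b]
                best_ll = np.where(b, ll, best_ll)
        with np.errstate(divide="ignore"):
            L = -0.75 * np.log(best_e)
        L[best_e >= 1.0] = 0.0
        L[best_e <= _E_LO] = L_CAP
        all_lengths[ti] = L
        all_ll[ti] = best_ll
    # Winner per replicate.  Exact ties (within 1e-9) are frequent at
    # saturation, where degenerate trees make distinct topologies realize
    # the same likelihood; they are split uniformly at random (seeded) --
    # a deterministic order would bias the tied-topology proportions --
    # and flagged.
    maxll = all_ll.max(axis=0)
    tied = all_ll >= maxll[None, :] - _TIE_TOL
    ks = tied.sum(axis=0)
    pick = (rng.random(R) * ks).astype(int)
    win = np.argmax(np.cumsum(tied, axis=0) > pick[None, :], axis=0)
    tie = ks > 1
    labels = np.empty(R, dtype="U1")
    y_frac = np.empty(R)
    z_frac = np.empty(R)
    y_sep = np.empty(R)
    for r in range(R):
        topo = TOPOLOGIES[win[r]]
        bl = all_lengths[win[r], r]
        labels[r] = _classify(topo, bl)
        y_frac[r], z_frac[r], y_sep[r] = _positions(topo, bl)
    return {
        "lengths": all_lengths,
        "loglik": all_ll,
        "winner": win,
        "labels": labels,
        "y_frac": y_frac,
        "z_frac": z_frac,
        "y_sep": y_sep,
        "tie": tie,
    }


def fit_quartet(
    counts: PatternCounts4, restarts: int = 5, seed: int | None = None
) -> QuartetFit:
    """ML fit of one quartet: all three topologies, best wins.

    Ties (log-likelihoods within 1e-9) are broken by the fixed topology
    order WY|XZ, WX|YZ, WZ|XY and flagged.
    """
    out = batched_fit_quartet(counts.as_array()[None, :], restarts=restarts, seed=seed)
    per = tuple(
        QuartetResult(t, tuple(out["lengths"][i, 0]), float(out["loglik"][i, 0]))
        for i, t in enumerate(TOPOLOGIES)
    )
    wi = int(out["winner"][0])
    return QuartetFit(
        per_topology=per,
        winner=per[wi],
        label=str(out["labels"][0]),
        y_frac=float(out["y_frac"][0]),
        z_frac=float(out["z_frac"][0]),
        y_sep=float(out["y_sep"][0]),
        tie=bool(out["tie"][0]),
        restarts=restarts,
    )


class QuartetML:
    """ML model for a four-taxon JC tree built from 15-class counts."""

    def __init__(self, counts: PatternCounts4):
        if counts.n == 0:
            raise ValueError("model requires n > 0 sites")
        self.counts = counts

    @classmethod
    def from_alignment(cls, seqs) -> "QuartetML":
        from .patterns import count_patterns

        return cls(count_patterns(seqs))

    def loglike(self, topology: str, lengths) -> float:
        return log_likelihood_4(self.counts, topology, lengths)

    def fit(self, restarts: int = 5, seed: int | None = None) -> QuartetFit:
        return fit_quartet(self.counts, restarts=restarts, seed=seed)


# ---------------------------------------------------------------------------
# Newick output.  Infinite branches are written with a sentinel length and a
# comment flag, zero branches as 0.0 exactly.
# ---------------------------------------------------------------------------

_INF_SENTINEL = 9999.0


def _fmt_len(d: float) -> str:
    if math.isinf(d):
        return f"{_INF_SENTINEL}[&infinite=true]"
    if d == 0.0:
        return "0.0"
    return f"{d:.8g}"


def newick_3(lengths, names=("A", "B", "C")) -> str:
    """Unrooted three-taxon tree as Newick."""
    parts = ",".join(f"{nm}:{_fmt_len(d)}" for nm, d in zip(names, lengths))
    return f"({parts});"


def newick_quartet(topology: str, lengths, names=("W", "X", "Y", "Z")) -> str:
    """Resolved quartet as Newick; branch order (b_W, b_X, b_Y, b_Z, b_int)."""
    (u1, u2), (v1, v2) = _NODE_TIPS[topology]
    bl = list(lengths)
    left = f"{names[u1]}:{_fmt_len(bl[u1])},{names[u2]}:{_fmt_len(bl[u2])}"
    right = f"{names[v1]}:{_fmt_len(bl[v1])},{names[v2]}:{_fmt_len(bl[v2])}"
    return f"(({left}):{_fmt_len(bl[4])},{right});"
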