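"""Maximum-likelihood branch lengths for the three-taxon JC tree.

The likelihood of three-taxon pattern counts is maximized over the closed
box [0, inf]^3 of branch lengths.  Parametrized by e_i = exp(-4 d_i / 3),
every pattern-class probability is multilinear in (e_A, e_B, e_C), so each
coordinate subproblem is the maximization of a sum of logs of linear
functions: a one-dimensional concave problem whose derivative is monotone.
Cyclic coordinate ascent with derivative bisection therefore reaches each
coordinate optimum to machine precision and detects the boundaries exactly
(e = 1 is d = 0; e -> 0 is d -> inf).  The search is batched across
replicates so whole simulation grids are fitted with vectorized numpy.

Boundary optima are central here: the analytic global and local maxima on
the faces of the solution space (identical-sequence pairs, zero planes,
infinite planes, the all-saturated corner) have closed forms in terms of JC
distance transforms of match fractions, and the numeric optimum is checked
against the infinite-branch candidates to confirm genuinely infinite
branches, whose placement on the tree is meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .distances import DistanceTriple, jc_distance, predict_anomalies
from .patterns import (
    INF,
    BranchLengths3,
    PatternCounts3,
    _class_probs_3_from_e,
    log_likelihood_3,
)

__all__ = [
    "MLResult",
    "ThreeTaxonML",
    "numeric_ml_3",
    "batched_numeric_ml_3",
    "global_boundary_solution",
    "local_boundary_maxima",
    "clock_plane_solution",
    "confirm_infinite",
    "ml_workflow",
    "position_on_path",
    "L_CAP",
    "INFINITE_CONFIRM_TOL",
]

#: Optimizer cap on finite branch lengths (expected substitutions/site).
#: The JC likelihood is flat beyond saturation; lengths at the cap are only
#: candidates for infinity, decided by the analytic comparison.
L_CAP = 50.0

#: Log-likelihood tolerance for confirming an infinite branch analytically.
INFINITE_CONFIRM_TOL = 1e-6

_E_LO = math.exp(-4.0 * L_CAP / 3.0)
_U_LO = math.log(_E_LO)


@dataclass(frozen=True)
class MLResult:
    """Outcome of a three-taxon ML fit.

    ``branch_lengths`` may contain 0.0 exactly (boundary optimum) or
    ``math.inf`` (confirmed infinite; its placement carries no information).
    ``provenance`` is one of ``global-boundary``, ``local-boundary``,
    ``clock-plane``, ``numeric``, ``analytic-infinite``.
    """

    branch_lengths: tuple
    loglik: float
    provenance: str
    zero_branches: frozenset = field(default=frozenset())
    infinite_branches: frozenset = field(default=frozenset())
    candidate_infinite: frozenset = field(default=frozenset())
    clock_symmetric: bool | None = None
    sum_identified: bool = False
    restarts: int = 0

    @property
    def branches(self) -> BranchLengths3:
        return BranchLengths3(*self.branch_lengths)

    def summary(self) -> str:
        names = ("d_A", "d_B", "d_C")
        lines = ["Three-taxon ML fit", "=" * 34]
        for nm, d in zip(names, self.branch_lengths):
            note = ""
            if d == 0.0:
                note = "  (boundary: zero)"
            elif math.isinf(d):
                note = "  (infinite: no meaningful position)"
            lines.append(f"{nm:>6}  {d:<12.6g}{note}")
        lines.append(f"log-likelihood  {self.loglik:.6f}")
        lines.append(f"solution        {self.provenance}")
        if self.sum_identified:
            lines.append("note: only the sum of the finite branches is identified")
        if self.clock_symmetric is not None:
            lines.append(f"clock-symmetric data (n_xyx = n_yxx): {self.clock_symmetric}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# 1-D concave subproblem: maximize sum_r n_r log(alpha_r + beta_r e), e in
# [e_lo, 1].  The derivative g(e) = sum n_r beta_r / (alpha_r + beta_r e) is
# monotone decreasing, so sign bisection (on u = ln e for uniform relative
# precision) is exact and fully vectorized.
# ---------------------------------------------------------------------------


def _grad_1d(nr, alpha, beta, e):
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = alpha + beta * e[..., None]
        terms = np.where(nr > 0, nr * beta / denom, 0.0)
    return terms.sum(axis=-1)


def _solve_1d(nr, alpha, beta, current_e, n_bisect=52):
    """Vectorized argmax of sum n log(alpha + beta e) over e in [_E_LO, 1]."""
    g_hi = _grad_1d(nr, alpha, beta, np.ones(len(nr)))
    g_lo = _grad_1d(nr, alpha, beta, np.full(len(nr), _E_LO))

    at_hi = (g_hi >= 0) & (g_lo > 0)
    at_lo = (g_lo <= 0) & (g_hi < 0)
    flat = (g_hi >= 0) & (g_lo <= 0)  # likelihood independent of e: keep
    interior = ~(at_hi | at_lo | flat)

    lo = np.full(len(nr), _U_LO)
    hi = np.zeros(len(nr))
    if interior.any():
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            pos = _grad_1d(nr, alpha, beta, np.exp(mid)) > 0
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
    e = np.exp(0.5 * (lo + hi))
    e = np.where(at_hi, 1.0, e)
    e = np.where(at_lo, _E_LO, e)
    e = np.where(flat, current_e, e)
    e[~interior & ~at_hi & ~at_lo & ~flat] = current_e[
        ~interior & ~at_hi & ~at_lo & ~flat
    ]  # NaN gradients (impossible data): do not move
    return e


def _loglik_rows(nr, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(nr > 0, nr * np.log(p), 0.0)
    return terms.sum(axis=1)


def _probs_3(e):
    return _class_probs_3_from_e(e[:, 0], e[:, 1], e[:, 2])


def _loglik_batch_3(nr, e):
    """Per-replicate log-likelihood; nr (R,5), e (R,3)."""
    return _loglik_rows(nr, _probs_3(e))


def _sweep(nr, e, probs_fn):
    """One cyclic coordinate-ascent sweep, exact 1-D solves, in place."""
    R, D = e.shape
    zero = np.zeros(R)
    one = np.ones(R)
    for i in range(D):
        cols = [e[:, j] for j in range(D)]
        cols_a = list(cols)
        cols_a[i] = zero
        alpha = probs_fn(cols_a)
        cols_b = list(cols)
        cols_b[i] = one
        beta = probs_fn(cols_b) - alpha
        e[:, i] = _solve_1d(nr, alpha, beta, e[:, i])
    return e


def _ascend(nr, e0, probs_fn, tol=1e-10, max_sweeps=400):
    """Coordinate ascent with pattern-move acceleration and convergence masking.

    ``probs_fn(list_of_coordinate_arrays) -> (R, K)`` per-specific-pattern
    class probabilities; must be multilinear in each coordinate so the 1-D
    subproblems are concave.  A line search along each sweep's displacement
    removes the zigzag that plain cyclic ascent suffers on correlated
    coordinates; replicates whose log-likelihood improves by less than
    ``tol`` are frozen.  A final plain sweep snaps boundary coordinates
    exactly (e = 1 means branch length 0).
    """
    e0 = np.atleast_2d(np.asarray(e0, float))
    D = e0.shape[1]
    e = np.broadcast_to(e0, (nr.shape[0], D)).copy()

    def probs_mat(em):
        return probs_fn([em[:, j] for j in range(D)])

    ll = _loglik_rows(nr, probs_mat(e))
    active = np.ones(nr.shape[0], bool)
    for _ in range(max_sweeps):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        sub = nr[idx]
        es = e[idx]
        e_prev = es.copy()
        _sweep(sub, es, probs_fn)
        # pattern move: extrapolate along the sweep displacement
        f_best = _loglik_rows(sub, probs_mat(es))
        step = es - e_prev
        for t in (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0):
            cand = np.clip(e_prev + t * step, _E_LO, 1.0)
            f = _loglik_rows(sub, probs_mat(cand))
            better = f > f_best
            if better.any():
                es[better] = cand[better]
                f_best = np.where(better, f, f_best)
        done = f_best - ll[idx] < tol
        e[idx] = es
        ll[idx] = f_best
        active[idx[done]] = False
    _sweep(nr, e, probs_fn)
    return e, _loglik_rows(nr, probs_mat(e))


def _starting_points(restarts: int, rng: np.random.Generator) -> np.ndarray:
    """The fixed start (0.1, 0.1, 0.1) plus log-uniform draws in [1e-3, 5]."""
    starts = [np.array([0.1, 0.1, 0.1])]
    for _ in range(restarts - 1):
        starts.append(np.exp(rng.uniform(math.log(1e-3), math.log(5.0), size=3)))
    return np.array(starts)


def _dm_start(nr: np.ndarray) -> np.ndarray:
    """Per-replicate start at the distance-matrix branch estimates.

    The exact three-point fit of the JC pairwise distances tracks the ML
    optimum closely, including its boundary structure, so starting there
    avoids the saturation plateaus that trap searches started far away.
    Saturated distances are capped and negative branches clipped to the
    lower box edge.
    """
    n = nr.sum(axis=1)
    U = np.stack(
        [
            (nr[:, 4] + nr[:, 2] + nr[:, 3]) / n,
            (nr[:, 1] + nr[:, 3] + nr[:, 4]) / n,
            (nr[:, 1] + nr[:, 2] + nr[:, 4]) / n,
        ],
        axis=1,
    )
    D = -0.75 * np.log1p(-4.0 * np.minimum(U, 0.7375) / 3.0)  # cap ~ 2.4
    d = 0.5 * np.stack(
        [
            D[:, 0] + D[:, 1] - D[:, 2],
            D[:, 0] + D[:, 2] - D[:, 1],
            D[:, 1] + D[:, 2] - D[:, 0],
        ],
        axis=1,
    )
    return np.clip(d, 1e-4, 10.0)


def batched_numeric_ml_3(
    counts: np.ndarray,
    restarts: int = 5,
    seed: int | None = None,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-start numeric ML for a batch of count vectors.

    Parameters
    ----------
    counts : (R, 5) array of class counts (order xxx, xxy, xyx, yxx, xyz).

    Returns
    -------
    lengths : (R, 3) branch lengths in [0, L_CAP]; exact 0.0 at boundary
        optima, L_CAP where the optimum ran to the cap (candidate infinite).
    loglik : (R,) best log-likelihood over the restarts.
    """
    nr = np.atleast_2d(np.asarray(counts, float))
    if nr.shape[1] != 5 or (nr < 0).any():
        raise ValueError("counts must be a (R, 5) array of non-negative counts")
    if (nr.sum(axis=1) <= 0).any():
        raise ValueError("each replicate needs n > 0 sites")
    rng = np.random.default_rng(seed)
    starts = list(_starting_points(max(1, restarts), rng))
    starts.append(_dm_start(nr))  # per-replicate distance-matrix start
    best_e = None
    best_ll = np.full(nr.shape[0], -np.inf)
    for d0 in starts:
        e0 = np.exp(-4.0 * np.asarray(d0) / 3.0)
        e, ll = _ascend(nr, e0, lambda cols: _class_probs_3_from_e(*cols), tol=tol)
        better = ll > best_ll
        if best_e is None:
            best_e, best_ll = e, ll
        else:
            best_e[better] = e[better]
            best_ll = np.where(better, ll, best_ll)
    with np.errstate(divide="ignore"):
        lengths = -0.75 * np.log(best_e)
    lengths[best_e >= 1.0] = 0.0
    lengths[best_e <= _E_LO] = L_CAP
    return lengths, best_ll


def numeric_ml_3(
    counts: PatternCounts3, restarts: int = 5, seed: int | None = None
) -> MLResult:
    """Multi-start numeric ML fit of one three-taxon count vector."""
    lengths, ll = batched_numeric_ml_3(
        counts.as_array()[None, :], restarts=restarts, seed=seed
    )
    d = tuple(float(x) for x in lengths[0])
    names = ("A", "B", "C")
    return MLResult(
        branch_lengths=d,
        loglik=float(ll[0]),
        provenance="numeric",
        zero_branches=frozenset(nm for nm, x in zip(names, d) if x == 0.0),
        candidate_infinite=frozenset(
            nm for nm, x in zip(names, d) if x >= L_CAP - 1e-9
        ),
        restarts=restarts,
    )


# ---------------------------------------------------------------------------
# Analytic boundary solutions
# ---------------------------------------------------------------------------


def _result(lengths, counts, provenance, **kw) -> MLResult:
    names = ("A", "B", "C")
    ll = log_likelihood_3(counts, BranchLengths3(*lengths))
    return MLResult(
        branch_lengths=tuple(lengths),
        loglik=ll,
        provenance=provenance,
        zero_branches=frozenset(nm for nm, d in zip(names, lengths) if d == 0.0),
        infinite_branches=frozenset(
            nm for nm, d in zip(names, lengths) if math.isinf(d)
        ),
        **kw,
    )


def global_boundary_solution(counts: PatternCounts3) -> MLResult | None:
    """Known global maxima when two sequences are identical.

    If all sites are constant the optimum is (0,0,0).  If a pair of taxa is
    identical (the three pattern classes separating them are empty), the two
    branches to that pair collapse to 0 and the third branch is the JC
    estimate from its match fraction -- infinite when matches <= n/4.
    Returns None when no such configuration holds.
    """
    n = counts.n
    if n == 0:
        raise ValueError("n must be > 0")
    if counts.n_xxx == n:
        return _result((0.0, 0.0, 0.0), counts, "global-boundary")
    # A == B identical: only xxx / xxy present; free branch is d_C
    if counts.n_xyz == counts.n_xyx == counts.n_yxx == 0:
        d = jc_distance(counts.n_xxy / n)
        return _result((0.0, 0.0, d), counts, "global-boundary")
    # A == C identical: only xxx / xyx present; free branch is d_B
    if counts.n_xyz == counts.n_yxx == counts.n_xxy == 0:
        d = jc_distance(counts.n_xyx / n)
        return _result((0.0, d, 0.0), counts, "global-boundary")
    # B == C identical: only xxx / yxx present; free branch is d_A
    if counts.n_xyz == counts.n_xxy == counts.n_xyx == 0:
        d = jc_distance(counts.n_yxx / n)
        return _result((d, 0.0, 0.0), counts, "global-boundary")
    return None


def local_boundary_maxima(counts: PatternCounts3) -> list[MLResult]:
    """Local maxima on the boundary of the solution space.

    Three zero-branch planes (the zeroed taxon sits at the internal node and
    the free branches take JC estimates from their match fractions, valid
    when both match counts exceed n/4), three infinite-branch planes (the
    saturated taxon is pure noise; only the *sum* of the two remaining
    branches is identified, equal to the JC distance of the remaining pair,
    valid when their matches exceed n/4), and the fully saturated corner
    (inf, inf, inf) with log-likelihood -n log 64, always a candidate.
    """
    n = counts.n
    if n == 0:
        raise ValueError("n must be > 0")
    m_ab = counts.n_xxx + counts.n_xxy  # A-B matches
    m_ac = counts.n_xxx + counts.n_xyx  # A-C matches
    m_bc = counts.n_xxx + counts.n_yxx  # B-C matches
    out: list[MLResult] = []
    q = n / 4.0
    # zero planes
    if m_ab > q and m_ac > q:
        out.append(
            _result(
                (0.0, jc_distance(1 - m_ab / n), jc_distance(1 - m_ac / n)),
                counts,
                "local-boundary",
            )
        )
    if m_ab > q and m_bc > q:
        out.append(
            _result(
                (jc_distance(1 - m_ab / n), 0.0, jc_distance(1 - m_bc / n)),
                counts,
                "local-boundary",
            )
        )
    if m_ac > q and m_bc > q:
        out.append(
            _result(
                (jc_distance(1 - m_ac / n), jc_distance(1 - m_bc / n), 0.0),
                counts,
                "local-boundary",
            )
        )
    # infinite planes: report the identified sum split evenly
    if m_bc > q:
        s = jc_distance(1 - m_bc / n)
        out.append(
            _result((INF, s / 2, s / 2), counts, "local-boundary", sum_identified=True)
        )
    if m_ac > q:
        s = jc_distance(1 - m_ac / n)
        out.append(
            _result((s / 2, INF, s / 2), counts, "local-boundary", sum_identified=True)
        )
    if m_ab > q:
        s = jc_distance(1 - m_ab / n)
        out.append(
            _result((s / 2, s / 2, INF), counts, "local-boundary", sum_identified=True)
        )
    out.append(_result((INF, INF, INF), counts, "local-boundary"))
    return out


def clock_plane_solution(counts: PatternCounts3) -> MLResult:
    """Constrained optimum on the molecular-clock plane d_A = d_B.

    Numeric restriction of the likelihood to two free parameters.  Flags
    whether the data are clock-symmetric (n_xyx = n_yxx), the case in which
    the branch to C lands exactly in the middle of the A-B path or at its
    edges.
    """
    from scipy.optimize import minimize

    nr = counts.as_array().astype(float)

    def negll(x):
        e_ab = math.exp(-4.0 * min(x[0], L_CAP) / 3.0)
        e_c = math.exp(-4.0 * min(x[1], L_CAP) / 3.0)
        p = _class_probs_3_from_e(e_ab, e_ab, e_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(nr > 0, nr * np.log(p), 0.0)
        s = terms.sum()
        return 1e30 if not np.isfinite(s) else -s

    best = None
    for x0 in ([0.1, 0.1], [0.1, 1.0], [0.5, 2.0]):
        r = minimize(negll, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        x = np.clip(r.x, 0.0, L_CAP)
        x[np.abs(x) < 1e-9] = 0.0
        if best is None or -negll(x) > best[1]:
            best = (x, -negll(x))
    x, ll = best
    res = _result((x[0], x[0], x[1]), counts, "clock-plane")
    return replace(
        res, loglik=ll, clock_symmetric=bool(counts.n_xyx == counts.n_yxx)
    )


#: Reference length at which the flat ridge left by an infinite branch is
#: profiled to take the limit of the finite-length optimum.
RIDGE_REF_D = 12.0


def _ridge_split_batch(nr: np.ndarray, k: int, s: np.ndarray, grid: int = 81):
    """Resolve the flat (a, b) ridge left by a confirmed infinite branch k.

    At the closure point the likelihood depends on the two remaining
    branches only through their sum s, but at any large finite length the
    first-order term breaks the tie; the limiting optimum is found by
    profiling along a + b = s with branch k at :data:`RIDGE_REF_D`.  Returns
    the length of the first non-infinite branch (exactly 0.0 at an edge).
    """
    f = np.linspace(0.0, 1.0, grid)
    a = f[None, :] * s[:, None]
    b = s[:, None] - a
    cols: list = [None, None, None]
    others = [i for i in range(3) if i != k]
    cols[others[0]] = np.exp(-4.0 * a / 3.0)
    cols[others[1]] = np.exp(-4.0 * b / 3.0)
    cols[k] = np.full_like(a, math.exp(-4.0 * RIDGE_REF_D / 3.0))
    p = _class_probs_3_from_e(*cols)  # (M, G, 5)
    nr3 = nr[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(nr3 > 0, nr3 * np.log(p), 0.0).sum(axis=-1)
    m = np.argmax(ll, axis=1)
    a_opt = f[m] * s
    a_opt[m == 0] = 0.0
    a_opt[m == grid - 1] = s[m == grid - 1]
    return a_opt


def confirm_infinite(
    counts: PatternCounts3, numeric: MLResult, tol: float = INFINITE_CONFIRM_TOL
) -> MLResult:
    """Decide whether a numeric optimum is in truth an infinite-branch tree.

    The log-likelihood of each analytic infinite-branch candidate is compared
    with the numeric optimum; a candidate at least as good (within ``tol``)
    confirms the infinity, since the numeric search can only approach the
    asymptote.  The confirmed branch has no meaningful position on the tree;
    the remaining pair, identified only through its summed length, is
    reported at the limit of the finite-length optimum (often a ridge edge,
    i.e. a zero branch).
    """
    cands = [
        c for c in local_boundary_maxima(counts) if c.infinite_branches
    ]
    best = max(cands, key=lambda c: c.loglik)
    if best.loglik < numeric.loglik - tol:
        return numeric
    if len(best.infinite_branches) == 1:
        k = "ABC".index(next(iter(best.infinite_branches)))
        others = [i for i in range(3) if i != k]
        s = sum(best.branch_lengths[i] for i in others)
        arr = counts.as_array().astype(float)[None, :]
        a = float(_ridge_split_batch(arr, k, np.array([s]))[0])
        lengths = [0.0, 0.0, 0.0]
        lengths[k] = INF
        lengths[others[0]] = a
        lengths[others[1]] = s - a
        best = _result(tuple(lengths), counts, "analytic-infinite", sum_identified=True)
        return replace(best, restarts=numeric.restarts)
    return replace(best, provenance="analytic-infinite", restarts=numeric.restarts)


def batched_confirm_infinite(
    counts: np.ndarray,
    lengths: np.ndarray,
    loglik: np.ndarray,
    tol: float = INFINITE_CONFIRM_TOL,
):
    """Vectorized boundary refinement + infinite-branch confirmation.

    Two stages for every replicate in the batch.  First the zero-plane
    analytic maxima (one branch collapsed, free branches at their JC
    estimates) replace the numeric optimum wherever they are strictly
    better.  Then the infinite-branch families ((inf,a,b) etc., valid when
    the remaining pair's match count exceeds n/4, and the all-saturated
    corner -n log 64) are compared with the refined optimum; confirmed
    replicates get exact ``inf`` lengths with the remaining pair resolved
    by the flat-ridge limit.

    Returns (lengths, loglik, confirmed) with confirmed a boolean mask.
    """
    nr = np.asarray(counts, float)
    R = nr.shape[0]
    n = nr.sum(axis=1)
    # matches of the pair left when branch k is infinite: A->(B,C), ...
    m = np.stack(
        [nr[:, 0] + nr[:, 3], nr[:, 0] + nr[:, 2], nr[:, 0] + nr[:, 1]]
    )  # (3, R)

    # Zero-plane analytic maxima first: with branch k collapsed, the free
    # branches take JC estimates from their match fractions (valid when
    # both exceed n/4).  Numeric searches started far away can miss these
    # when the accompanying free branch is nearly saturated, so the exact
    # candidates refine the numeric fit before any infinity is judged.
    m_ab, m_ac, m_bc = m[2], m[1], m[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        e_pair = np.stack(
            [
                (4.0 * m_ab / n - 1.0) / 3.0,
                (4.0 * m_ac / n - 1.0) / 3.0,
                (4.0 * m_bc / n - 1.0) / 3.0,
            ]
        )  # e = exp(-4 d_hat / 3) of each pair's JC estimate
    ones = np.ones(R)
    zp_cols = {
        0: (ones, e_pair[0], e_pair[1]),  # d_A = 0: free (d_B, d_C)
        1: (e_pair[0], ones, e_pair[2]),  # d_B = 0
        2: (e_pair[1], e_pair[2], ones),  # d_C = 0
    }
    zp_valid = {
        0: (m_ab > n / 4.0) & (m_ac > n / 4.0),
        1: (m_ab > n / 4.0) & (m_bc > n / 4.0),
        2: (m_ac > n / 4.0) & (m_bc > n / 4.0),
    }
    lengths = np.asarray(lengths, float).copy()
    loglik = np.asarray(loglik, float).copy()
    for k in range(3):
        eA, eB, eC = zp_cols[k]
        p = _class_probs_3_from_e(eA, eB, eC)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_zp = np.where(nr > 0, nr * np.log(p), 0.0).sum(axis=1)
        better = zp_valid[k] & (ll_zp > loglik)
        if better.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                d_free = -0.75 * np.log(np.stack([eA, eB, eC], axis=1))
            d_free[:, k] = 0.0
            lengths[better] = d_free[better]
            loglik[better] = ll_zp[better]
    with np.errstate(divide="ignore", invalid="ignore"):
        fam = (
            -n * math.log(16.0)
            + np.where(m > 0, m * np.log(m / n), 0.0)
            + np.where(n - m > 0, (n - m) * np.log((n - m) / (3.0 * n)), 0.0)
        )
    fam = np.where(m > n / 4.0, fam, -np.inf)
    all_inf = np.full(R, 1.0) * (-n * math.log(64.0))
    cand = np.vstack([fam, all_inf])  # (4, R)
    best_idx = np.argmax(cand, axis=0)
    best_val = cand[best_idx, np.arange(R)]
    confirmed = best_val >= loglik - tol

    out_lengths = np.asarray(lengths, float).copy()
    out_ll = np.where(confirmed, best_val, loglik)
    for k in range(3):
        sel = confirmed & (best_idx == k)
        if not sel.any():
            continue
        e_s = (4.0 * m[k, sel] / n[sel] - 1.0) / 3.0
        s = -0.75 * np.log(e_s)
        a = _ridge_split_batch(nr[sel], k, s)
        others = [i for i in range(3) if i != k]
        rows = np.where(sel)[0]
        out_lengths[rows, k] = np.inf
        out_lengths[rows, others[0]] = a
        out_lengths[rows, others[1]] = s - a
    sel = confirmed & (best_idx == 3)
    out_lengths[sel] = np.inf
    return out_lengths, out_ll, confirmed


def ml_workflow(
    counts: PatternCounts3,
    restarts: int = 5,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MLResult:
    """Combined ML/DM workflow for the three-taxon ML solution.

    1. Return a known global boundary maximum if one applies.
    2. Otherwise, if the distance-matrix conditions predict a zero or
       infinite branch, return the best matching analytic boundary solution
       (a measured-accuracy heuristic).
    3. Otherwise run the multi-start numeric search with infinite-branch
       confirmation.

    ``exhaustive`` additionally always runs the numeric search and keeps the
    better optimum.
    """
    g = global_boundary_solution(counts)
    if g is not None:
        return g
    pred = predict_anomalies(DistanceTriple.from_counts(counts))
    analytic = None
    if pred.any_zero or pred.any_infinite:
        cands = local_boundary_maxima(counts)
        matching = [
            c
            for c in cands
            if (c.zero_branches & pred.zero)
            or (c.infinite_branches & pred.infinite)
            or (pred.at_least_two_infinite and len(c.infinite_branches) >= 2)
        ]
        if matching:
            analytic = max(matching, key=lambda c: c.loglik)
    if analytic is not None and not exhaustive:
        return analytic
    numeric = confirm_infinite(
        counts, numeric_ml_3(counts, restarts=restarts, seed=seed)
    )
    if analytic is not None and analytic.loglik >= numeric.loglik:
        return analytic
    return numeric


def position_on_path(d_A: float, d_B: float) -> float:
    """Attachment point of the third taxon as a fraction along the A-B path.

    0 means at A's end (d_A = 0), 1 at B's end.  NaN when undefined (both
    branches zero) or excluded (either branch infinite).
    """
    if math.isinf(d_A) or math.isinf(d_B):
        return math.nan
    if d_A == 0.0 and d_B == 0.0:
        return math.nan
    return d_A / (d_A + d_B)


class ThreeTaxonML:
    """ML branch-length model for a three-taxon JC tree.

    Built from pattern-class counts (the sufficient statistics); ``fit``
    returns an :class:`MLResult`.

    Parameters
    ----------
    counts : PatternCounts3
        Class counts of the alignment, taxa in order (A, B, C).
    """

    def __init__(self, counts: PatternCounts3):
        if counts.n == 0:
            raise ValueError("model requires n > 0 sites")
        self.counts = counts

    @classmethod
    def from_alignment(cls, seqs) -> "ThreeTaxonML":
        from .patterns import count_patterns

        return cls(count_patterns(seqs))

    def loglike(self, branches) -> float:
        return log_likelihood_3(self.counts, branches)

    def fit(
        self,
        method: str = "workflow",
        restarts: int = 5,
        seed: int | None = None,
        exhaustive: bool = False,
    ) -> MLResult:
        """Fit branch lengths.

        method : "workflow" (analytic shortcuts + numeric fallback, default),
        "numeric" (multi-start search + infinite confirmation) or "clock"
        (restriction to the d_A = d_B plane).
        """
        if method == "workflow":
            return ml_workflow(
                self.counts, restarts=restarts, seed=seed, exhaustive=exhaustive
            )
        if method == "numeric":
            return confirm_infinite(
                self.counts, numeric_ml_3(self.counts, restarts=restarts, seed=seed)
            )
        if method == "clock":
            return clock_plane_solution(self.counts)
        raise ValueError(f"unknown method {method!r}")
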