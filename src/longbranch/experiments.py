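"""Drivers for the simulation experiments: long-branch placement on
three-taxon trees, distance-matrix prediction accuracy, zero-branch
frequency tables, and the long-branch-closeness (LBC) and
long-branch-joining (LBJ) analyses on quartets.

Each driver simulates its grid, runs pure numeric multi-start ML with
analytic infinite-branch confirmation (the distance-matrix shortcut is
deliberately *not* used for the ML columns, so DM-vs-ML accuracy
measurements are not circular), and returns tidy DataFrames.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .ml import batched_confirm_infinite, batched_numeric_ml_3
from .patterns import CLASS_NAMES_4, _pattern_class
from .quartet import batched_fit_quartet
from .simulate import (
    QuartetTree,
    SimConfig,
    ThreeTaxonTree,
    simulate_counts_3,
    simulate_counts_4,
)
from .variance import predict_zero_proportion

__all__ = [
    "dm_predict_batch",
    "fit_ml_batch_3",
    "run_fig3",
    "run_fig5",
    "run_table4",
    "run_lbc",
    "run_lbj",
    "marginal_counts_3",
]

_BASES = "ACGT"


def _seeds(seed, k: int):
    if seed is None:
        return [None] * k
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(k) >> 1]


def dm_predict_batch(counts: np.ndarray) -> dict:
    """Distance-matrix anomaly predictions for a batch of count vectors.

    Vectorized version of ``predict_anomalies``: returns boolean arrays
    ``zero_any`` (a zero branch predicted via a triangle-inequality /
    one-infinite-distance condition) and ``inf_any`` (two or more infinite
    distances: an infinite branch predicted).
    """
    nr = np.asarray(counts, float)
    n = nr.sum(axis=1)
    U = np.stack(
        [
            (nr[:, 4] + nr[:, 2] + nr[:, 3]) / n,  # AB
            (nr[:, 1] + nr[:, 3] + nr[:, 4]) / n,  # AC
            (nr[:, 1] + nr[:, 2] + nr[:, 4]) / n,  # BC
        ]
    )
    sat = U >= 0.75
    with np.errstate(divide="ignore"):
        D = np.where(sat, np.inf, -0.75 * np.log1p(-4.0 * np.minimum(U, 0.749999) / 3.0))
    n_inf = sat.sum(axis=0)
    zero = (
        (D[2] >= D[0] + D[1]) | (D[1] >= D[0] + D[2]) | (D[0] >= D[1] + D[2])
    )
    zero_any = zero & (n_inf < 2)
    inf_any = n_inf >= 2
    return {"zero_any": zero_any, "inf_any": inf_any, "n_inf_distances": n_inf}


def fit_ml_batch_3(
    counts: np.ndarray, seed=None, restarts: int = 5
) -> dict:
    """Numeric multi-start ML + infinite confirmation for a count batch.

    Returns lengths (R,3) with exact 0.0 / inf entries, log-likelihoods,
    and boolean masks ``zero_any`` / ``inf_any``.
    """
    lengths, ll = batched_numeric_ml_3(counts, restarts=restarts, seed=seed)
    lengths, ll, confirmed = batched_confirm_infinite(counts, lengths, ll)
    return {
        "lengths": lengths,
        "loglik": ll,
        "zero_any": (lengths == 0.0).any(axis=1),
        "inf_any": np.isinf(lengths).any(axis=1),
    }


def _positions_ab(lengths: np.ndarray) -> np.ndarray:
    """Fraction of C's attachment along the A-B path; NaN when excluded
    (any infinite branch) or undefined (d_A = d_B = 0)."""
    dA, dB = lengths[:, 0], lengths[:, 1]
    bad = np.isinf(lengths).any(axis=1) | ((dA == 0) & (dB == 0))
    with np.errstate(invalid="ignore"):
        pos = np.where(bad, np.nan, dA / (dA + dB))
    return pos


def run_fig3(
    seed=None,
    reps: int = 5000,
    n: int = 300,
    d_ab: float = 0.1,
    d_c_grid=(0.1, 0.5, 1.0, 1.25, 1.5, 2.0),
    restarts: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Placement of the long branch C on the A-B path.

    Returns (records, summary): per-replicate positions with ML and DM
    flags, and a per-d_C summary with infinite/zero counts.  Infinite-branch
    trees have NaN positions (excluded from the histograms).
    """
    cells = list(d_c_grid)
    recs = []
    for dc, s in zip(cells, _seeds(seed, len(cells))):
        s_sim, s_fit = _seeds(s, 2)
        counts = simulate_counts_3(SimConfig(ThreeTaxonTree(d_ab, d_ab, dc), n=n, reps=reps, seed=s_sim))
        fit = fit_ml_batch_3(counts, seed=s_fit, restarts=restarts)
        dm = dm_predict_batch(counts)
        recs.append(
            pd.DataFrame(
                {
                    "d_C": dc,
                    "replicate": np.arange(reps),
                    "position": _positions_ab(fit["lengths"]),
                    "ml_zero": fit["zero_any"],
                    "ml_infinite": fit["inf_any"],
                    "dm_zero_pred": dm["zero_any"],
                    "dm_inf_pred": dm["inf_any"],
                }
            )
        )
    records = pd.concat(recs, ignore_index=True)
    summary = (
        records.groupby("d_C")
        .agg(
            n_infinite=("ml_infinite", "sum"),
            n_zero=("ml_zero", "sum"),
            n_plotted=("position", lambda x: int(x.notna().sum())),
        )
        .reset_index()
    )
    return records, summary


def run_fig5(
    seed=None,
    reps: int = 5000,
    n: int = 300,
    d_ab_grid=(0.05, 0.1, 0.2, 0.3),
    d_c_grid=(0.1, 0.5, 1.0, 1.25, 1.5, 2.0),
    restarts: int = 5,
) -> pd.DataFrame:
    """Accuracy of the DM conditions as predictors of ML outcomes.

    Per cell: ``zero_accuracy`` = (true positives + true negatives) / total
    for the zero-branch prediction, evaluated over replicates whose ML tree
    has no confirmed infinite branch (a branch of infinite length has no
    meaningful position, so the zero/non-zero status of the remaining pair
    is an artifact of the flat ridge; the infinite-branch prediction task
    is scored separately), and ``inf_accuracy`` for the infinite-branch
    prediction over all replicates.
    """
    cells = [(dab, dc) for dab in d_ab_grid for dc in d_c_grid]
    rows = []
    for (dab, dc), s in zip(cells, _seeds(seed, len(cells))):
        s_sim, s_fit = _seeds(s, 2)
        counts = simulate_counts_3(SimConfig(ThreeTaxonTree(dab, dab, dc), n=n, reps=reps, seed=s_sim))
        fit = fit_ml_batch_3(counts, seed=s_fit, restarts=restarts)
        dm = dm_predict_batch(counts)
        finite = ~fit["inf_any"]
        rows.append(
            {
                "d_AB": dab,
                "d_C": dc,
                "zero_accuracy": float(
                    np.mean(dm["zero_any"][finite] == fit["zero_any"][finite])
                ),
                "inf_accuracy": float(np.mean(dm["inf_any"] == fit["inf_any"])),
                "ml_zero_prop": float(fit["zero_any"].mean()),
                "dm_zero_prop": float(dm["zero_any"].mean()),
                "ml_inf_count": int(fit["inf_any"].sum()),
                "dm_inf_count": int(dm["inf_any"].sum()),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


def run_table4(
    seed=None,
    reps: int = 5000,
    n: int = 300,
    d_ab: float = 0.1,
    d_c_grid=(0.1, 0.5, 1.0, 1.25, 1.5, 2.0),
    restarts: int = 5,
) -> pd.DataFrame:
    """Zero-branch proportions: normal-approximation prediction vs DM vs ML.

    One row per d_C with columns ``predicted`` (delta-method normal
    approximation), ``dm`` (fraction of replicates triggering a zero
    condition), ``ml`` (fraction of ML trees with a zero branch, all
    replicates in the denominator) and ``ml_inf_count``.
    """
    rows = []
    for dc, s in zip(d_c_grid, _seeds(seed, len(d_c_grid))):
        s_sim, s_fit = _seeds(s, 2)
        counts = simulate_counts_3(SimConfig(ThreeTaxonTree(d_ab, d_ab, dc), n=n, reps=reps, seed=s_sim))
        fit = fit_ml_batch_3(counts, seed=s_fit, restarts=restarts)
        dm = dm_predict_batch(counts)
        rows.append(
            {
                "d_C": dc,
                "predicted": predict_zero_proportion((d_ab, d_ab, dc), n).p_zero,
                "dm": float(dm["zero_any"].mean()),
                "ml": float(fit["zero_any"].mean()),
                "ml_inf_count": int(fit["inf_any"].sum()),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Quartet experiments
# ---------------------------------------------------------------------------

# class-marginalization matrices: 15-class quartet counts -> 5-class counts
# of a taxon triple, built from class representatives
_IDX3 = {"xxx": 0, "xxy": 1, "xyx": 2, "xyy": 3, "xyz": 4}


def _marginal_matrix(keep: tuple) -> np.ndarray:
    reps = {}
    import itertools

    for pat in itertools.product(_BASES, repeat=4):
        reps.setdefault(_pattern_class(pat), pat)
    P = np.zeros((15, 5))
    for i, cls in enumerate(CLASS_NAMES_4):
        sub = [reps[cls][k] for k in keep]
        P[i, _IDX3[_pattern_class(sub)]] = 1.0
    return P


_P_WXY = _marginal_matrix((0, 1, 2))
_P_WXZ = _marginal_matrix((0, 1, 3))


def marginal_counts_3(counts4: np.ndarray, keep=(0, 1, 2)) -> np.ndarray:
    """Collapse 15-class quartet counts to the 5-class counts of a triple.

    ``keep`` are taxon indices in (W, X, Y, Z) order; the kept taxa take
    the roles (A, B, C)."""
    P = _marginal_matrix(tuple(keep))
    return np.asarray(counts4, float) @ P


def run_lbc(
    seed=None,
    length: float = 1.5,
    reps: int = 5000,
    n: int = 1000,
    restarts: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-branch closeness measurement.

    Each replicate from the quartet tree is fitted as the two three-taxon
    trees (W,X,Y) and (W,X,Z) and as the best four-taxon tree.  ``x`` is
    the separation of Z's and Y's positions on the W-X path from the
    three-taxon fits, ``y`` the (signed) separation on the winning quartet
    (0 for outcomes d/f).  Under LBC the correct topology's points would
    fall below the x = y line.

    Returns (records, stats); stats has, per resolved topology, the exact
    binomial test of points strictly below vs strictly above x = y and the
    correlation of Y's three- vs four-taxon positions.
    """
    s_sim, s_fit3y, s_fit3z, s_fit4 = _seeds(seed, 4)
    counts4 = simulate_counts_4(SimConfig(QuartetTree(length), n=n, reps=reps, seed=s_sim))
    fit_y = fit_ml_batch_3(counts4 @ _P_WXY, seed=s_fit3y, restarts=restarts)
    fit_z = fit_ml_batch_3(counts4 @ _P_WXZ, seed=s_fit3z, restarts=restarts)
    q = batched_fit_quartet(counts4, restarts=restarts, seed=s_fit4)
    pos_y3 = _positions_ab(fit_y["lengths"])
    pos_z3 = _positions_ab(fit_z["lengths"])
    records = pd.DataFrame(
        {
            "replicate": np.arange(reps),
            "length": length,
            "pos_y3": pos_y3,
            "pos_z3": pos_z3,
            "x": pos_z3 - pos_y3,
            "y": q["y_sep"],
            "pos_y4": q["y_frac"],
            "pos_z4": q["z_frac"],
            "label": q["labels"],
            "tie": q["tie"],
        }
    )
    stats = []
    for lab in ("c", "e"):
        sub = records[(records["label"] == lab)].dropna(subset=["x", "y"])
        below = int((sub["y"] < sub["x"]).sum())
        above = int((sub["y"] > sub["x"]).sum())
        pval = (
            binomtest(below, below + above).pvalue if below + above > 0 else math.nan
        )
        corr = (
            float(np.corrcoef(sub["pos_y3"], sub["pos_y4"])[0, 1])
            if len(sub) > 1
            else math.nan
        )
        stats.append(
            {
                "label": lab,
                "n": len(sub),
                "below_xy": below,
                "above_xy": above,
                "binom_p": pval,
                "corr_y3_y4": corr,
            }
        )
    return records, pd.DataFrame(stats)


def run_lbj(
    seed=None,
    lengths=(0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0),
    reps: int = 2000,
    n: int = 1000,
    restarts: int = 5,
) -> pd.DataFrame:
    """Long-branch joining: topology proportions vs long-branch length.

    Per length: proportions of outcomes c (correct), d (long branches
    joined), e (swapped) and f (star).  The asymptote is read at the
    largest simulated length, with a leveling check (change from the
    previous length within 2 binomial SE) and the c-vs-e equality check of
    the saturation limit argument.
    """
    rows = []
    for L, s in zip(lengths, _seeds(seed, len(lengths))):
        s_sim, s_fit = _seeds(s, 2)
        counts4 = simulate_counts_4(SimConfig(QuartetTree(L), n=n, reps=reps, seed=s_sim))
        q = batched_fit_quartet(counts4, restarts=restarts, seed=s_fit)
        labs = q["labels"]
        row = {"length": L, "reps": reps, "tie_prop": float(q["tie"].mean())}
        for lab in "cdef":
            row[f"prop_{lab}"] = float(np.mean(labs == lab))
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("length").reset_index(drop=True)
    if len(df) >= 2:
        last, prev = df.iloc[-1], df.iloc[-2]
        se = math.sqrt(0.25 / last["reps"])
        df.attrs["leveled_off"] = bool(
            abs(last["prop_d"] - prev["prop_d"]) < 2 * se
        )
        nc = int(last["prop_c"] * last["reps"])
        ne = int(last["prop_e"] * last["reps"])
        df.attrs["c_vs_e_binom_p"] = (
            binomtest(nc, nc + ne).pvalue if nc + ne > 0 else math.nan
        )
    return df
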