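"""Delta-method variance of distance-based branch estimates and the
normal-approximation prediction of zero-branch frequency.

The three mismatch fractions (U_AB, U_AC, U_BC) are linear in the
multinomial pattern-class frequencies, so their exact covariance follows
from the multinomial covariance (cross-covariances included: the three
distances share sequences).  The delta method through the JC transform
D = -(3/4) ln(1 - 4U/3) gives the covariance of the distance estimates,
and the three-point formulas d_A = (D_AB + D_AC - D_BC)/2 (and the B
analogue) propagate it to the tip-branch estimates.  Treating each
estimate as normal with mean at the true length, the predicted proportion
of datasets with a zero-length branch is P(d_A <= 0) + P(d_B <= 0); the
two events are mutually exclusive up to a negligible set when the true
d_A, d_B are positive.  Everything is evaluated at the *true* class
probabilities: the prediction is a function of the three branch lengths
and the sequence length only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .patterns import BranchLengths3, pattern_class_probs_3

__all__ = ["VariancePrediction", "distance_covariance", "predict_zero_proportion"]

# pair membership of the 5 classes (xxx, xxy, xyx, yxx, xyz): 1 where the
# pair mismatches
_M = np.array(
    [
        [0, 0, 1, 1, 1],  # A-B
        [0, 1, 0, 1, 1],  # A-C
        [0, 1, 1, 0, 1],  # B-C
    ],
    dtype=float,
)


def _true_U(branches: BranchLengths3) -> np.ndarray:
    return _M @ pattern_class_probs_3(branches)


def distance_covariance(branches, n: int) -> np.ndarray:
    """Exact delta-method covariance of (D_AB, D_AC, D_BC) estimates.

    ``branches`` are the true lengths; ``n`` the number of sites.  The
    diagonal reduces to the classical JC variance
    U(1-U) / (n (1-4U/3)^2).  Raises if a true mismatch fraction is at or
    beyond saturation (infinite variance).
    """
    if not isinstance(branches, BranchLengths3):
        branches = BranchLengths3(*branches)
    if n < 1:
        raise ValueError("n must be >= 1")
    p = pattern_class_probs_3(branches)
    U = _M @ p
    if any(math.isinf(d) for d in branches.as_tuple()) or (U >= 0.75).any():
        # U reaches 3/4 only in the infinite-branch limit, where the
        # distance estimate has infinite variance
        raise ValueError(
            "a true mismatch fraction is at saturation (U >= 3/4): the "
            "distance estimate has infinite variance"
        )
    cov_U = _M @ (np.diag(p) - np.outer(p, p)) @ _M.T / n
    J = np.diag(1.0 / (1.0 - 4.0 * U / 3.0))
    return J @ cov_U @ J


@dataclass(frozen=True)
class VariancePrediction:
    """Normal-approximation prediction of the zero-branch proportion."""

    branches: tuple
    n: int
    cov_D: np.ndarray
    var_d_A: float
    var_d_B: float
    p_zero_A: float
    p_zero_B: float

    @property
    def p_zero(self) -> float:
        """Predicted proportion of datasets with d_A or d_B inferred <= 0."""
        return self.p_zero_A + self.p_zero_B

    def summary(self) -> str:
        dA, dB, dC = self.branches
        return "\n".join(
            [
                "Zero-branch frequency prediction (normal approximation)",
                "=" * 56,
                f"true tree (d_A, d_B, d_C) = ({dA}, {dB}, {dC}), n = {self.n}",
                f"sd(d_A_hat) = {math.sqrt(self.var_d_A):.5f}   "
                f"P(d_A_hat <= 0) = {self.p_zero_A:.4f}",
                f"sd(d_B_hat) = {math.sqrt(self.var_d_B):.5f}   "
                f"P(d_B_hat <= 0) = {self.p_zero_B:.4f}",
                f"predicted zero-branch proportion = {self.p_zero:.4f}",
            ]
        )


def predict_zero_proportion(branches, n: int) -> VariancePrediction:
    """Predict the proportion of datasets whose fitted tree has a zero
    branch to A or B, from the true tree and the sequence length."""
    if not isinstance(branches, BranchLengths3):
        branches = BranchLengths3(*branches)
    cov_D = distance_covariance(branches, n)
    w_A = np.array([0.5, 0.5, -0.5])
    w_B = np.array([0.5, -0.5, 0.5])
    var_A = float(w_A @ cov_D @ w_A)
    var_B = float(w_B @ cov_D @ w_B)
    p_A = float(norm.cdf(-branches.d_A / math.sqrt(var_A))) if var_A > 0 else 0.0
    p_B = float(norm.cdf(-branches.d_B / math.sqrt(var_B))) if var_B > 0 else 0.0
    return VariancePrediction(
        branches=branches.as_tuple(),
        n=int(n),
        cov_D=cov_D,
        var_d_A=var_A,
        var_d_B=var_B,
        p_zero_A=p_A,
        p_zero_B=p_B,
    )
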