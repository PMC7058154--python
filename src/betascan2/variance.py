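"""Closed-form variances of the beta statistics and standardization.

Every statistic in this package is linear in the unfolded site frequency
spectrum of the window: writing xi_k for the number of window SNPs with
derived count k (k = 1..n-1), each of theta_watterson, theta_beta,
beta(1) and beta(1)* equals sum_k omega_k * xi_k for a vector of class
weights omega.  The variance of such a statistic under the neutral
coalescent is

    Var = theta * sum_k omega_k^2 / k  +  theta^2 * omega' Sigma omega

where theta is the per-window mutation rate and Sigma collects the
second-order covariances of the class counts.  Two models for Sigma are
provided:

* ``"coalescent"`` (default) — the exact second moments of SFS class
  counts for a non-recombining window under the neutral coalescent
  (Fu's sigma matrix).  Sites in a short window share one genealogy, so
  their counts are positively correlated; this is the appropriate model
  for the window sizes the scan uses.
* ``"poisson"`` — independent sites (free recombination): Sigma = 0, so
  Var = theta * sum_k omega_k^2 / k.  A lower bound, useful for data
  with high recombination relative to window size.

The substitution-based estimator theta_D = D/C is independent of the
polymorphism part; modeling D as Poisson with neutral mean theta*C gives
Var[theta_D] = theta / C, and Var[beta(2)] = Var[theta_beta] +
Var[theta_D] (the two parts are uncorrelated).

Standardized scores are beta / sqrt(Var); because every beta statistic
has expectation zero under neutrality no centering term is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .estimators import (
    WeightSpec,
    harmonic,
    similarity_weight,
    theta_beta_normalizer,
)
from .io_formats import BetaScanError

__all__ = [
    "VarianceResult",
    "fu_sigma",
    "omega_for_statistic",
    "variance_linear_sfs",
    "variance_theta_D",
    "variance_beta",
    "standardize",
]

VARIANCE_MODELS = ("coalescent", "poisson")


@dataclass(frozen=True)
class VarianceResult:
    """Variance of a linear SFS statistic, split by order in theta.

    ``var_total = lin_coef * theta + quad_coef * theta**2``.
    """

    var_total: float
    lin_coef: float
    quad_coef: float


def _a(n: int) -> float:
    return harmonic(n)


def _beta_fu(n: int, i: int) -> float:
    # second-moment helper for the coalescent SFS, defined for 1 <= i <= n-1
    return 2.0 * n * (_a(n + 1) - _a(i)) / ((n - i + 1) * (n - i)) - 2.0 / (n - i)


@lru_cache(maxsize=64)
def fu_sigma(n: int) -> np.ndarray:
    """Quadratic-coefficient matrix Sigma for the coalescent SFS.

    Cov[xi_i, xi_j] = delta_ij * theta/i + Sigma_ij * theta^2 for a
    non-recombining neutral window of sample size n.  Satisfies
    sum_ij Sigma_ij == sum_k 1/k^2 (the classical Var[S] identity).
    """
    if n < 2:
        raise BetaScanError(f"sample size must be >= 2, got {n}")
    an = _a(n)
    sig = np.zeros((n - 1, n - 1))
    for i in range(1, n):
        if 2 * i < n:
            s = _beta_fu(n, i + 1)
        elif 2 * i == n:
            s = 2.0 * (an - _a(i)) / (n - i) - 1.0 / i**2
        else:
            s = _beta_fu(n, i) - 1.0 / i**2
        sig[i - 1, i - 1] = s
    for i in range(2, n):
        for j in range(1, i):
            if i + j < n:
                s = (_beta_fu(n, i + 1) - _beta_fu(n, i)) / 2.0
            elif i + j == n:
                s = (
                    (an - _a(i)) / (n - i)
                    + (an - _a(j)) / (n - j)
                    - (_beta_fu(n, i) + _beta_fu(n, j + 1)) / 2.0
                    - 1.0 / (i * j)
                )
            else:
                s = (_beta_fu(n, j) - _beta_fu(n, j + 1)) / 2.0 - 1.0 / (i * j)
            sig[i - 1, j - 1] = sig[j - 1, i - 1] = s
    sig.setflags(write=False)
    return sig


def omega_for_statistic(
    statistic_name: str, spec: Optional[WeightSpec], n: int
) -> np.ndarray:
    """Per-class weights omega such that the statistic is omega . xi.

    Supported names: ``theta_w``, ``theta_beta``, ``B1``, ``B1star`` and
    ``B2`` (whose polymorphism part is theta_beta; the substitution term
    is handled separately).  For folded statistics classes k and n-k
    carry equal weight.
    """
    if n < 2:
        raise BetaScanError(f"sample size must be >= 2, got {n}")
    ks = np.arange(1, n)
    if statistic_name == "theta_w":
        return np.full(n - 1, 1.0 / harmonic(n))
    if spec is None:
        raise BetaScanError(f"statistic {statistic_name!r} needs a weight spec")
    folded = spec.folded
    f = np.minimum(ks, n - ks) / n if folded else ks / n
    omega_tb = np.asarray(similarity_weight(f, spec)) / theta_beta_normalizer(spec, n)
    if statistic_name in ("theta_beta", "B2"):
        if statistic_name == "B2" and folded:
            raise BetaScanError("B2 requires an unfolded weight spec")
        return omega_tb
    if statistic_name == "B1":
        if folded:
            raise BetaScanError("B1 requires an unfolded weight spec")
        return omega_tb - 1.0 / harmonic(n)
    if statistic_name == "B1star":
        if not folded:
            raise BetaScanError("B1star requires a folded weight spec")
        return omega_tb - 1.0 / harmonic(n)
    raise BetaScanError(f"unknown statistic {statistic_name!r}")


def variance_linear_sfs(
    omega: np.ndarray, theta: float, n: int, model: str = "coalescent"
) -> VarianceResult:
    """Variance of sum_k omega_k xi_k on a window with per-window theta."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (n - 1,):
        raise BetaScanError(f"omega must have {n - 1} entries, got shape {omega.shape}")
    if not np.any(omega):
        raise BetaScanError("degenerate omega (all zeros)")
    if not theta > 0:
        raise BetaScanError(f"theta must be > 0, got {theta}")
    if model not in VARIANCE_MODELS:
        raise BetaScanError(f"unknown variance model {model!r}")
    ks = np.arange(1, n)
    lin = float(np.sum(omega**2 / ks))
    quad = float(omega @ fu_sigma(n) @ omega) if model == "coalescent" else 0.0
    return VarianceResult(var_total=lin * theta + quad * theta**2, lin_coef=lin, quad_coef=quad)


def variance_theta_D(theta: float, C: float) -> float:
    """Var[theta_D] = theta / C under D ~ Poisson(theta * C)."""
    if not C > 0:
        raise BetaScanError(f"divergence scalar C must be > 0, got {C}")
    if not theta > 0:
        raise BetaScanError(f"theta must be > 0, got {theta}")
    return theta / C


def variance_beta(
    statistic_name: str,
    spec: Optional[WeightSpec],
    theta: float,
    n: int,
    C: Optional[float] = None,
    model: str = "coalescent",
) -> float:
    """Variance of a beta statistic at per-window theta.

    For ``B2`` this is Var[theta_beta] + Var[theta_D] (Var of a
    difference of independent parts); for ``B1`` and ``B1star`` the
    difference omega vector already carries the covariance between
    theta_beta and theta_watterson, which share the same class counts.
    """
    if statistic_name == "B2":
        if C is None:
            raise BetaScanError("B2 variance requires the divergence scalar C")
        poly = variance_linear_sfs(
            omega_for_statistic("theta_beta", spec, n), theta, n, model
        ).var_total
        return poly + variance_theta_D(theta, C)
    omega = omega_for_statistic(statistic_name, spec, n)
    return variance_linear_sfs(omega, theta, n, model).var_total


def standardize(beta_value: float, variance: float) -> float:
    """Standardized score beta / sqrt(variance); requires variance > 0."""
    if not variance > 0:
        raise BetaScanError(f"variance must be > 0, got {variance}")
    return beta_value / float(np.sqrt(variance))
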