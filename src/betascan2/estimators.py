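"""Mutation-rate estimators and the raw beta statistics.

Each beta statistic contrasts two estimators of the population-scaled
mutation rate theta computed on the sites in a window around a core SNP:

* ``theta_beta`` — a frequency-similarity-weighted count of SNPs; inflated
  when linked variants cluster at the core SNP's frequency, the footprint
  of two long-lived allelic classes.
* ``theta_watterson`` — the classical estimator from the number of
  segregating sites, insensitive to the shape of the frequency spectrum.
* ``theta_D`` — an estimator from the number of substitutions D relative
  to an outgroup, ``D / C`` with ``C = T/(2*Ne) + 1/n``; deflated when an
  old balanced polymorphism has prevented fixation.

The statistics::

    beta1      = theta_beta (unfolded) - theta_watterson
    beta1_star = theta_beta (folded)   - theta_watterson
    beta2      = theta_beta (unfolded) - theta_D

All three have expectation zero under neutrality and are positive when
variation has built up at the core frequency (and, for beta2, when
substitutions are depleted).

All theta values in this module are per-window totals, not per bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .io_formats import BetaScanError

__all__ = [
    "WeightSpec",
    "WindowCounts",
    "ScanParams",
    "harmonic",
    "similarity_weight",
    "theta_watterson",
    "theta_beta",
    "theta_beta_normalizer",
    "theta_beta_from_spectrum",
    "theta_D",
    "divergence_scalar",
    "beta1",
    "beta1_star",
    "beta2",
]


@dataclass(frozen=True)
class WeightSpec:
    """Similarity-weight configuration for one core SNP.

    A window SNP at frequency ``f`` receives weight
    ``(1 - |f - x| / max_diff) ** p`` where ``x`` is the core frequency
    and ``max_diff`` is the largest possible frequency difference
    (1.0 unfolded, 0.5 folded).  ``p`` controls how sharply weight
    concentrates on frequencies near ``x``; larger values demand closer
    frequency matching.
    """

    x: float
    p: float = 2.0
    folded: bool = False

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise BetaScanError(f"sharpness p must be > 0, got {self.p}")
        upper = 0.5 if self.folded else 1.0
        if not (0.0 < self.x <= upper) or (not self.folded and self.x >= 1.0):
            raise BetaScanError(
                f"core frequency {self.x} outside (0, {upper}{']' if self.folded else ')'}"
            )

    @property
    def max_diff(self) -> float:
        return 0.5 if self.folded else 1.0


@dataclass(frozen=True)
class WindowCounts:
    """Aggregated contents of one scan window (core SNP excluded).

    ``freqs`` are the frequencies of the informative polymorphic SNPs
    (derived-allele fractions if unfolded, minor-allele fractions if
    folded), ``D`` the number of substitutions, ``n`` the sample size
    used for normalization constants and ``span`` the window length in bp.
    """

    freqs: np.ndarray
    D: int
    n: int
    span: int
    folded: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        if self.n < 2:
            raise BetaScanError(f"sample size must be >= 2, got {self.n}")
        if self.D < 0:
            raise BetaScanError(f"substitution count must be >= 0, got {self.D}")
        f = self.freqs
        upper = 0.5 if self.folded else 1.0
        if f.size and (np.any(f <= 0.0) or np.any(f > upper) or
                       (not self.folded and np.any(f >= 1.0))):
            raise BetaScanError("window frequencies outside the admissible range")

    @property
    def S(self) -> int:
        return int(self.freqs.size)


@dataclass(frozen=True)
class ScanParams:
    """Nuisance parameters shared across a scan.

    ``theta`` is the per-bp mutation-scaled diversity, ``C`` the
    divergence scalar ``T/(2*Ne) + 1/n`` converting substitution counts
    to theta units, ``n`` the sample size, ``window`` the window width in
    bp, ``p`` the weight sharpness and ``min_core_freq`` the minimum
    folded frequency for a core SNP to be scored.
    """

    theta: float
    n: int
    C: Optional[float] = None
    window: int = 1000
    p: float = 2.0
    min_core_freq: float = 0.05

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise BetaScanError(f"theta must be > 0, got {self.theta}")
        if self.n < 2:
            raise BetaScanError(f"sample size must be >= 2, got {self.n}")
        if self.C is not None and not self.C > 1.0 / self.n:
            raise BetaScanError(f"divergence scalar C must exceed 1/n, got {self.C}")
        if self.window < 2:
            raise BetaScanError(f"window must be >= 2 bp, got {self.window}")
        if not (0.0 <= self.min_core_freq < 0.5):
            raise BetaScanError(f"min_core_freq must be in [0, 0.5), got {self.min_core_freq}")


def harmonic(n: int) -> float:
    """The Watterson constant a_n = sum_{k=1}^{n-1} 1/k (a_1 = 0)."""
    return float(np.sum(1.0 / np.arange(1, n)))


def similarity_weight(
    f: Union[float, np.ndarray], spec: WeightSpec
) -> Union[float, np.ndarray]:
    """Weight ``(1 - |f - x| / max_diff) ** p`` for frequency ``f``.

    Equals 1 at ``f == x`` and falls to 0 at the maximum possible
    frequency difference.  Raises if any ``|f - x|`` exceeds
    ``max_diff`` (inadmissible frequency for this mode).
    """
    f_arr = np.asarray(f, dtype=float)
    diff = np.abs(f_arr - spec.x)
    if np.any(diff > spec.max_diff + 1e-12):
        raise BetaScanError(
            f"frequency difference exceeds max_diff={spec.max_diff} for core x={spec.x}"
        )
    w = np.clip(1.0 - diff / spec.max_diff, 0.0, 1.0) ** spec.p
    return float(w) if np.isscalar(f) or f_arr.ndim == 0 else w


def theta_watterson(S: int, n: int) -> float:
    """Watterson's estimator S / a_n (per window)."""
    if n < 2:
        raise BetaScanError(f"sample size must be >= 2, got {n}")
    if S < 0:
        raise BetaScanError(f"segregating-site count must be >= 0, got {S}")
    if S == 0:
        return 0.0
    return S / harmonic(n)


def theta_beta_normalizer(spec: WeightSpec, n: int) -> float:
    """Denominator making theta_beta unbiased for theta per window.

    Under neutrality the expected number of SNPs at derived count k is
    theta/k, so the weighted SNP count has expectation
    theta * sum_k w(k/n)/k; dividing by that sum (with folded classes k
    and n-k merged, the middle class counted once for even n) yields an
    unbiased estimator.
    """
    if n < 2:
        raise BetaScanError(f"sample size must be >= 2, got {n}")
    if spec.folded:
        ks = np.arange(1, n // 2 + 1)
        w = similarity_weight(ks / n, spec)
        terms = w * (1.0 / ks + 1.0 / (n - ks))
        terms = np.where(2 * ks == n, terms / 2.0, terms)
        return float(np.sum(terms))
    ks = np.arange(1, n)
    return float(np.sum(similarity_weight(ks / n, spec) / ks))


def theta_beta(win: WindowCounts, spec: WeightSpec) -> float:
    """Similarity-weighted theta estimate for one window.

    Returns ``sum_i w(f_i) / normalizer``; 0 on an empty window.  Folded
    windows must be paired with a folded spec and vice versa.
    """
    if win.folded != spec.folded:
        raise BetaScanError("window and weight spec disagree on folding")
    if win.S == 0:
        return 0.0
    num = float(np.sum(similarity_weight(win.freqs, spec)))
    return num / theta_beta_normalizer(spec, win.n)


def theta_beta_from_spectrum(xi: np.ndarray, spec: WeightSpec, n: int) -> float:
    """theta_beta evaluated on unfolded class counts xi_1..xi_{n-1}.

    Accepts fractional counts (e.g. an expected spectrum).  Folded specs
    fold the classes before weighting.
    """
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (n - 1,):
        raise BetaScanError(f"expected {n - 1} class counts, got shape {xi.shape}")
    ks = np.arange(1, n)
    f = np.minimum(ks, n - ks) / n if spec.folded else ks / n
    num = float(np.sum(similarity_weight(f, spec) * xi))
    return num / theta_beta_normalizer(spec, n)


def theta_D(D: float, C: float) -> float:
    """Substitution-based theta estimate D / C with C = T/(2*Ne) + 1/n."""
    if not C > 0:
        raise BetaScanError(f"divergence scalar C must be > 0, got {C}")
    if D < 0:
        raise BetaScanError(f"substitution count must be >= 0, got {D}")
    return D / C


def divergence_scalar(t_div: float, ne: float, n: int) -> float:
    """C = T/(2*Ne) + 1/n from divergence time T (generations), Ne and n."""
    if t_div <= 0 or ne <= 0 or n < 2:
        raise BetaScanError("need t_div > 0, Ne > 0 and n >= 2")
    return t_div / (2.0 * ne) + 1.0 / n


def beta1(win: WindowCounts, spec: WeightSpec) -> float:
    """beta(1) = theta_beta - theta_watterson on unfolded data."""
    if spec.folded or win.folded:
        raise BetaScanError("beta1 requires unfolded data; use beta1_star for folded")
    return theta_beta(win, spec) - theta_watterson(win.S, win.n)


def beta1_star(win: WindowCounts, spec: WeightSpec) -> float:
    """beta(1)* = theta_beta - theta_watterson on a folded spectrum."""
    if not (spec.folded and win.folded):
        raise BetaScanError("beta1_star requires folded data; use beta1 for unfolded")
    return theta_beta(win, spec) - theta_watterson(win.S, win.n)


def beta2(win: WindowCounts, spec: WeightSpec, C: float) -> float:
    """beta(2) = theta_beta - theta_D; needs polarized data + substitutions."""
    if spec.folded or win.folded:
        raise BetaScanError("beta2 requires polarized (unfolded) data")
    return theta_beta(win, spec) - theta_D(win.D, C)
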