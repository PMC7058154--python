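"""Synthetic inputs and Monte-Carlo oracles.

Two positional generators emit site lists in the scan input format:

* :func:`gen_neutral` — a neutral window: the number of SNPs is
  Poisson(theta * a_n), each SNP's derived count k is drawn with
  probability proportional to 1/k (the neutral frequency spectrum),
  substitutions are Poisson(theta * C), and positions are uniform
  without collision.  Class counts are independent across sites, i.e.
  this is the free-recombination null.
* :func:`gen_balanced` — a window carrying the footprint of long-term
  balancing selection at equilibrium frequency ``x_eq``: a tunable
  fraction of SNPs sits at the balanced frequency (variants fixed within
  an allelic class all surface at that class's frequency), the
  substitution rate is multiplied by ``sub_deficit`` (old balanced
  polymorphism suppresses fixation), and a core SNP at ``x_eq`` is
  guaranteed at the window midpoint.

For variance work the module also samples site-frequency-spectrum class
counts directly, under either window model:

* ``"coalescent"`` — one non-recombining genealogy per window, simulated
  with msprime; mutations are then dropped as Poisson counts on the
  branch-length spectrum.  Class counts are positively correlated, as in
  a real window.
* ``"poisson"`` — independent Poisson(theta/k) class counts, the
  free-recombination model matching :func:`gen_neutral`.

:func:`monte_carlo_variance` estimates the mean and variance of any beta
statistic over replicate neutral windows and is the simulation oracle the
closed-form variances are checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import msprime
import numpy as np

from .estimators import WeightSpec, harmonic
from .io_formats import BetaScanError, SiteRecord
from .variance import omega_for_statistic

__all__ = [
    "NeutralGenSpec",
    "BalancedGenSpec",
    "MonteCarloResult",
    "gen_neutral",
    "gen_balanced",
    "coalescent_branch_spectra",
    "sample_neutral_spectra",
    "monte_carlo_variance",
    "partial_auc",
]


@dataclass(frozen=True)
class NeutralGenSpec:
    """Parameters of a neutral window: per-bp theta, span (bp), sample
    size n, divergence scalar C and RNG seed."""

    theta_bp: float
    span: int
    n: int
    C: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_bp <= 0 or self.span <= 0 or self.n < 2 or self.C <= 0:
            raise BetaScanError("NeutralGenSpec fields must be positive (n >= 2)")

    @property
    def theta_window(self) -> float:
        return self.theta_bp * self.span


@dataclass(frozen=True)
class BalancedGenSpec:
    """Parameters of a balanced-locus window.

    ``x_eq`` is the equilibrium frequency; ``class_frac`` the fraction of
    SNPs fixed within an allelic class (and hence at ``x_eq``);
    ``sub_deficit`` multiplies the neutral substitution rate (< 1 models
    the fixation deficit); ``class_noise`` adds binomial sampling noise
    to the balanced-class counts.
    """

    x_eq: float
    theta_bp: float
    span: int
    n: int
    C: float
    sub_deficit: float = 0.2
    class_frac: float = 0.8
    class_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.x_eq < 1.0):
            raise BetaScanError(f"x_eq must be in (0,1), got {self.x_eq}")
        if not (0.0 <= self.sub_deficit <= 1.0) or not (0.0 <= self.class_frac <= 1.0):
            raise BetaScanError("sub_deficit and class_frac must be in [0,1]")
        if self.theta_bp <= 0 or self.span <= 0 or self.n < 2 or self.C <= 0:
            raise BetaScanError("BalancedGenSpec fields must be positive (n >= 2)")
        k0 = round(self.x_eq * self.n)
        if k0 <= 0 or k0 >= self.n:
            raise BetaScanError(
                f"equilibrium frequency {self.x_eq} is inadmissible at n={self.n}"
            )

    @property
    def theta_window(self) -> float:
        return self.theta_bp * self.span


def _neutral_class_probs(n: int) -> np.ndarray:
    ks = np.arange(1, n)
    p = 1.0 / ks
    return p / p.sum()


def _draw_positions(rng: np.random.Generator, span: int, size: int,
                    reserved: Optional[int] = None) -> np.ndarray:
    pool = span - (1 if reserved is not None else 0)
    if size > pool:
        raise BetaScanError(f"cannot place {size} distinct sites in span {span}")
    pos = rng.choice(pool, size=size, replace=False) + 1
    if reserved is not None:
        pos = np.where(pos >= reserved, pos + 1, pos)
    return np.sort(pos)


def gen_neutral(spec: NeutralGenSpec) -> List[SiteRecord]:
    """Simulate one neutral window as a position-sorted site list."""
    rng = np.random.default_rng(spec.seed)
    theta = spec.theta_window
    S = rng.poisson(theta * harmonic(spec.n))
    D = rng.poisson(theta * spec.C)
    counts = np.concatenate([
        rng.choice(np.arange(1, spec.n), size=S, p=_neutral_class_probs(spec.n)),
        np.full(D, spec.n, dtype=int),
    ])
    rng.shuffle(counts)
    positions = _draw_positions(rng, spec.span, S + D)
    return [
        SiteRecord(position=int(p), count=int(c), n=spec.n)
        for p, c in zip(positions, counts)
    ]


def _balanced_counts(rng: np.random.Generator, size: int, spec: BalancedGenSpec) -> np.ndarray:
    k0 = round(spec.x_eq * spec.n)
    if not spec.class_noise:
        return np.full(size, k0, dtype=int)
    counts = rng.binomial(spec.n, spec.x_eq, size=size)
    # condition on segregating: redraw until every count is in 1..n-1
    bad = (counts <= 0) | (counts >= spec.n)
    while np.any(bad):
        counts[bad] = rng.binomial(spec.n, spec.x_eq, size=int(bad.sum()))
        bad = (counts <= 0) | (counts >= spec.n)
    return counts


def gen_balanced(spec: BalancedGenSpec) -> List[SiteRecord]:
    """Simulate one balanced-locus window as a position-sorted site list.

    A core SNP at count ``round(x_eq * n)`` is placed at the window
    midpoint; each other SNP is balanced-class with probability
    ``class_frac`` and neutral otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    theta = spec.theta_window
    n = spec.n
    S = rng.poisson(theta * harmonic(n))
    D = rng.poisson(theta * spec.C * spec.sub_deficit)
    n_bal = rng.binomial(S, spec.class_frac)
    counts = np.concatenate([
        _balanced_counts(rng, n_bal, spec),
        rng.choice(np.arange(1, n), size=S - n_bal, p=_neutral_class_probs(n)),
        np.full(D, n, dtype=int),
    ])
    rng.shuffle(counts)
    core_pos = spec.span // 2
    positions = _draw_positions(rng, spec.span, S + D, reserved=core_pos)
    records = [
        SiteRecord(position=int(p), count=int(c), n=n)
        for p, c in zip(positions, counts)
    ]
    core = SiteRecord(position=core_pos, count=round(spec.x_eq * n), n=n)
    records.append(core)
    records.sort(key=lambda r: r.position)
    return records


def coalescent_branch_spectra(n: int, replicates: int, seed: int) -> np.ndarray:
    """Branch-length frequency spectra of non-recombining genealogies.

    Returns a ``(replicates, n-1)`` array whose row r, entry k-1 is the
    total branch length subtending k of the n samples, in coalescent
    time units (pairwise coalescence rate 1), so that dropping mutations
    as Poisson(theta/2 * length) gives E[xi_k] = theta/k.
    """
    if n < 2:
        raise BetaScanError(f"sample size must be >= 2, got {n}")
    out = np.empty((replicates, n - 1))
    sims = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0,
        num_replicates=replicates, random_seed=max(1, seed),
    )
    for i, ts in enumerate(sims):
        afs = ts.allele_frequency_spectrum(
            mode="branch", polarised=True, span_normalise=True
        )
        out[i] = afs[1:n]
    return out


def sample_neutral_spectra(
    n: int,
    theta: float,
    replicates: int,
    seed: int,
    model: str = "coalescent",
) -> np.ndarray:
    """Sample unfolded class-count vectors xi for replicate neutral windows.

    ``theta`` is per window.  Under ``"coalescent"`` the counts within a
    window share one genealogy (linked sites); under ``"poisson"`` they
    are independent Poisson(theta/k).
    """
    rng = np.random.default_rng(seed)
    if model == "coalescent":
        L = coalescent_branch_spectra(n, replicates, seed=seed % (2**31 - 2) + 1)
        return rng.poisson(theta / 2.0 * L)
    if model == "poisson":
        ks = np.arange(1, n)
        return rng.poisson(theta / ks, size=(replicates, n - 1))
    raise BetaScanError(f"unknown window model {model!r}")


def partial_auc(pos_scores, neg_scores, max_fpr: float = 0.05) -> float:
    """Raw partial area under the ROC curve up to ``max_fpr``.

    ``pos_scores`` come from windows carrying the signal (true positives),
    ``neg_scores`` from neutral windows.  The maximum attainable value is
    ``max_fpr`` itself (perfect separation).  Used by the power analyses
    comparing statistics on matched balanced/neutral replicates.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise BetaScanError("need scores from both classes")
    if not (0.0 < max_fpr <= 1.0):
        raise BetaScanError(f"max_fpr must be in (0, 1], got {max_fpr}")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tpr = np.concatenate([[0.0], np.cumsum(labels) / pos.size])
    fpr = np.concatenate([[0.0], np.cumsum(1.0 - labels) / neg.size])
    boundary_tpr = np.interp(max_fpr, fpr, tpr)
    keep = fpr <= max_fpr
    return float(np.trapezoid(np.append(tpr[keep], boundary_tpr),
                              np.append(fpr[keep], max_fpr)))


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical mean and variance of a statistic over neutral windows,
    with batch-means standard errors (10 batches)."""

    mean: float
    variance: float
    se_mean: float
    se_variance: float
    replicates: int


def monte_carlo_variance(
    statistic_name: str,
    gen_spec: NeutralGenSpec,
    weight_spec: Optional[WeightSpec],
    replicates: int,
    model: str = "coalescent",
) -> MonteCarloResult:
    """Simulate a beta statistic (or theta estimator) on neutral windows.

    Exploits linearity: each statistic is omega . xi, minus D/C for B2
    with D ~ Poisson(theta * C) independent of the polymorphism part.
    Requires at least 1000 replicates for stable batch-means errors.
    """
    if replicates < 1000:
        raise BetaScanError(f"need >= 1000 replicates, got {replicates}")
    n, theta = gen_spec.n, gen_spec.theta_window
    xi = sample_neutral_spectra(n, theta, replicates, seed=gen_spec.seed, model=model)
    if statistic_name == "B2":
        omega = omega_for_statistic("theta_beta", weight_spec, n)
    else:
        omega = omega_for_statistic(statistic_name, weight_spec, n)
    values = xi @ omega
    if statistic_name == "B2":
        rng = np.random.default_rng((gen_spec.seed + 1) % 2**31)
        D = rng.poisson(theta * gen_spec.C, size=replicates)
        values = values - D / gen_spec.C
    batches = np.array_split(values, 10)
    batch_means = np.array([b.mean() for b in batches])
    batch_vars = np.array([b.var(ddof=1) for b in batches])
    return MonteCarloResult(
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        se_mean=float(batch_means.std(ddof=1) / np.sqrt(len(batches))),
        se_variance=float(batch_vars.std(ddof=1) / np.sqrt(len(batches))),
        replicates=replicates,
    )
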