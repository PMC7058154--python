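"""Genome scan orchestration.

Workflow: read sites, settle the nuisance parameters (per-bp theta and,
for beta(2), the divergence scalar C), then slide a window over every
eligible core SNP, compute the chosen beta statistic on the window
contents, attach its closed-form variance and standardized score, and
optionally rank all scores into empirical genome-wide percentiles.

Windows are half-open intervals ``[pos - window/2, pos + window/2)``
around each core; the core itself never contributes to its own window.
Cores with folded frequency below ``min_core_freq`` are skipped: the
theoretical frequency spectrum is a poor description of rare variants in
real data, and balanced alleles are not maintained at extreme
frequencies, so rare cores add noise without adding power.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from . import estimators as est
from .estimators import WeightSpec, WindowCounts
from .io_formats import BetaScanError, ScoreRow, SiteRecord
from .variance import standardize, variance_beta

__all__ = [
    "ScanConfig",
    "estimate_theta",
    "estimate_divergence_scalar",
    "iterate_windows",
    "scan",
    "score_locus",
    "empirical_percentiles",
    "attach_percentiles",
]

STATISTICS = ("B1", "B1star", "B2")


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings.

    ``theta`` is the per-bp mutation rate; leave ``None`` to estimate it
    from the input (Watterson over all polymorphic sites / span).  ``C``
    is the divergence scalar ``T/(2*Ne) + 1/n``; leave ``None`` to
    estimate it as the genome-wide ratio of substitutions to Watterson's
    theta (required only for B2).  ``variance_model`` selects the
    coalescent (linked-sites, default) or poisson (independent-sites)
    second moments for standardization.
    """

    statistic: str = "B2"
    window: int = 1000
    p: float = 2.0
    min_core_freq: float = 0.05
    theta: Optional[float] = None
    C: Optional[float] = None
    standardize: bool = True
    variance_model: str = "coalescent"

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise BetaScanError(f"unknown statistic {self.statistic!r}")
        if self.window < 2:
            raise BetaScanError(f"window must be >= 2 bp, got {self.window}")
        if not (0.0 <= self.min_core_freq < 0.5):
            raise BetaScanError(f"min_core_freq must be in [0, 0.5), got {self.min_core_freq}")

    @property
    def folded(self) -> bool:
        return self.statistic == "B1star"


def _modal_n(sites: Sequence[SiteRecord]) -> int:
    if not sites:
        raise BetaScanError("no sites")
    return Counter(rec.n for rec in sites).most_common(1)[0][0]


def estimate_theta(
    sites: Sequence[SiteRecord], n: Optional[int] = None, total_span: Optional[int] = None
) -> float:
    """Per-bp Watterson estimate over all polymorphic sites.

    ``total_span`` defaults to the spanned interval
    ``max(position) - min(position) + 1``.
    """
    poly = [rec for rec in sites if rec.folded or rec.count < rec.n]
    if not poly:
        raise BetaScanError("cannot estimate theta: no polymorphic sites")
    if n is None:
        n = _modal_n(poly)
    if total_span is None:
        total_span = sites[-1].position - sites[0].position + 1
    if total_span <= 0:
        raise BetaScanError(f"total_span must be > 0, got {total_span}")
    return est.theta_watterson(len(poly), n) / total_span


def estimate_divergence_scalar(sites: Sequence[SiteRecord], n: Optional[int] = None) -> float:
    """Estimate C = T/(2*Ne) + 1/n as D_total / theta_W_total.

    This is the scalar that makes the genome-wide substitution-based
    theta estimate agree with genome-wide Watterson's theta, as it must
    under neutrality.  Requires unfolded input with at least one
    substitution and one polymorphic site.
    """
    if any(rec.folded for rec in sites):
        raise BetaScanError("divergence scalar needs unfolded (polarized) input")
    D_total = sum(1 for rec in sites if rec.is_substitution)
    S_total = len(sites) - D_total
    if D_total == 0 or S_total == 0:
        raise BetaScanError(
            "cannot estimate the divergence scalar without both substitutions and "
            "SNPs; supply the divergence time T and Ne instead"
        )
    if n is None:
        n = _modal_n(sites)
    return D_total / est.theta_watterson(S_total, n)


def iterate_windows(
    sites: Sequence[SiteRecord], config: ScanConfig
) -> Iterator[Tuple[SiteRecord, WindowCounts]]:
    """Yield (core SNP, window contents) for every eligible core.

    Eligible cores are polymorphic sites with folded frequency >=
    ``min_core_freq``.  The window is the half-open interval
    ``[pos - window/2, pos + window/2)`` excluding the core itself.
    """
    if not sites:
        return
    positions = np.array([rec.position for rec in sites])
    is_sub = np.array([rec.is_substitution for rec in sites])
    freqs = np.array([rec.folded_freq if config.folded else rec.freq for rec in sites])
    half = config.window // 2
    for i, rec in enumerate(sites):
        if is_sub[i] or rec.folded_freq < config.min_core_freq:
            continue
        lo = np.searchsorted(positions, rec.position - half, side="left")
        hi = np.searchsorted(positions, rec.position + half, side="left")
        idx = np.arange(lo, hi)
        idx = idx[idx != i]
        sub_mask = is_sub[idx]
        yield rec, WindowCounts(
            freqs=freqs[idx][~sub_mask],
            D=int(sub_mask.sum()) if config.statistic == "B2" else 0,
            n=rec.n,
            span=config.window,
            folded=config.folded,
        )


def _core_x(rec: SiteRecord, folded: bool) -> float:
    return rec.folded_freq if folded else rec.freq


@lru_cache(maxsize=4096)
def _cached_variance(
    statistic: str, x: float, p: float, folded: bool,
    theta_window: float, n: int, C: Optional[float], model: str,
) -> float:
    spec = WeightSpec(x=x, p=p, folded=folded)
    return variance_beta(statistic, spec, theta_window, n, C=C, model=model)


def _score_window(
    position: int, win: WindowCounts, x: float, config: ScanConfig, theta_bp: float
) -> ScoreRow:
    spec = WeightSpec(x=x, p=config.p, folded=config.folded)
    if config.statistic == "B1":
        value = est.beta1(win, spec)
    elif config.statistic == "B1star":
        value = est.beta1_star(win, spec)
    else:
        value = est.beta2(win, spec, config.C)
    theta_window = theta_bp * win.span
    var = _cached_variance(
        config.statistic, x, config.p, config.folded,
        theta_window, win.n, config.C, config.variance_model,
    )
    beta_std = standardize(value, var)
    return ScoreRow(
        position=position,
        statistic_name=config.statistic,
        beta=value,
        variance=var,
        beta_std=beta_std,
    )


def _resolve_params(sites: Sequence[SiteRecord], config: ScanConfig) -> ScanConfig:
    if config.theta is None:
        config = replace(config, theta=estimate_theta(sites))
    if config.statistic == "B2" and config.C is None:
        config = replace(config, C=estimate_divergence_scalar(sites))
    if config.standardize and config.theta is None:
        raise BetaScanError("standardization requires a theta source")
    return config


def scan(sites: Sequence[SiteRecord], config: ScanConfig) -> List[ScoreRow]:
    """Score every eligible core SNP; returns position-sorted rows."""
    if config.statistic == "B2" and any(rec.folded for rec in sites):
        raise BetaScanError("B2 requires unfolded (polarized) input with substitutions")
    if config.folded and sites and not sites[0].folded:
        raise BetaScanError("B1star requires folded input (read with folded=True)")
    if not sites:
        return []
    config = _resolve_params(sites, config)
    rows = [
        _score_window(core.position, win, _core_x(core, config.folded), config, config.theta)
        for core, win in iterate_windows(sites, config)
    ]
    return rows


def _modal_frequency(freqs: np.ndarray) -> float:
    """Most common frequency; ties broken toward 0.5, then the smaller."""
    values, counts = np.unique(freqs, return_counts=True)
    best = values[counts == counts.max()]
    dist = np.abs(best - 0.5)
    best = best[dist == dist.min()]
    return float(best.min())


def score_locus(
    sites: Sequence[SiteRecord],
    start: int,
    end: int,
    config: ScanConfig,
    core_freq: Optional[float] = None,
) -> ScoreRow:
    """Score one predefined interval ``[start, end)`` as a single window.

    Standardization makes the score comparable across window sizes, so a
    locus of interest can be tested directly without a sliding scan.  The
    core frequency defaults to the modal SNP frequency in the interval;
    all interval SNPs (there is no physical core to exclude) contribute.
    The row's position is the interval midpoint.
    """
    if end <= start:
        raise BetaScanError(f"empty interval [{start}, {end})")
    config = _resolve_params(sites, config)
    in_locus = [rec for rec in sites if start <= rec.position < end]
    poly = [rec for rec in in_locus if rec.folded or rec.count < rec.n]
    if not poly:
        raise BetaScanError("no polymorphic sites in the locus")
    freqs = np.array([rec.folded_freq if config.folded else rec.freq for rec in poly])
    x = core_freq if core_freq is not None else _modal_frequency(freqs)
    win = WindowCounts(
        freqs=freqs,
        D=sum(1 for rec in in_locus if rec.is_substitution) if config.statistic == "B2" else 0,
        n=_modal_n(poly),
        span=end - start,
        folded=config.folded,
    )
    return _score_window((start + end) // 2, win, x, config, config.theta)


def empirical_percentiles(values: Sequence[float]) -> np.ndarray:
    """Midrank empirical percentiles in (0, 1] over the given scores."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return arr
    return rankdata(arr, method="average") / arr.size


def attach_percentiles(rows: Sequence[ScoreRow]) -> List[ScoreRow]:
    """Return rows with the genome-wide percentile of beta_std filled in."""
    pct = empirical_percentiles([row.beta_std for row in rows])
    return [replace(row, percentile=float(q)) for row, q in zip(rows, pct)]
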