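# Methods

This document records the statistical model behind `betascan2`, the meaning
and default of every user-facing parameter, what the synthetic generators do
and do not emulate, the numerical conventions, and the known limitations.
The README covers usage; this covers *why*.

## 1. Model and statistics

### 1.1 Setting

A sample of *n* haploid genomes (chromosomes) is summarised per site by the
derived-allele count *k* ∈ {1, …, n−1} (unfolded) or the minor-allele count
*k* ∈ {1, …, ⌊n/2⌋} (folded). Sites with *k = n* in unfolded data are
substitutions relative to the outgroup. Under the standard neutral
coalescent the expected count of unfolded frequency class *k* in a region is
E[ξ_k] = θ/k, where θ = 4Nₑµ is the population-scaled mutation rate of the
region.

### 1.2 Estimators of θ

Every estimator used here is linear in the site-frequency spectrum (SFS):
θ̂ = Σ_k ω_k ξ_k for some weight vector ω, chosen so that Σ_k ω_k/k = 1
(unbiasedness on E[ξ_k] = θ/k).

- **Watterson:** ω_k = 1/a_n with a_n = Σ_{i=1}^{n−1} 1/i, i.e.
  θ̂_W = S / a_n with S the number of segregating sites.
- **Frequency-similarity weighted:** for a core SNP at frequency *x*, weight
  each variant at frequency *f = k/n* by

      w(f) = (1 − |f − x| / m)^p ,

  with *m* = 1 (unfolded) or *m* = 0.5 (folded), and normalise:

      θ̂_β = Σ_k w(k/n) ξ_k / Σ_k w(k/n) / k            (unfolded)

  In folded data the class *k* aggregates unfolded classes *k* and *n−k*,
  so the normaliser is Σ_{k ≤ n/2} w(k/n) (1/k + 1/(n−k)) / (1 + 𝟙[k = n−k]);
  the indicator halves the middle class at even *n*, which would otherwise
  be counted twice.
- **Divergence-based:** the substitution count *D* in a region has
  expectation θ·C with

      C = T / (2Nₑ) + 1/n ,

  (*T* = divergence time in generations; the 1/n term is the expected time
  for the sample to reach its common ancestor, beyond which the lineage is
  shared with the outgroup branch). Hence θ̂_D = D / C.

### 1.3 The β statistics

- β(1) = θ̂_β − θ̂_W (unfolded),
- β(1)\* = the same contrast with folded weights and normaliser,
- β(2) = θ̂_β − θ̂_D (unfolded, needs substitutions).

All three have expectation 0 under neutrality for every *x*, *p*, *n*. Near
a balanced polymorphism θ̂_β rises (trapped variants cluster near *x*) while
θ̂_W rises less and θ̂_D falls (substitution deficit), so the statistics go
positive. The core SNP itself is excluded from its own window so that the
score measures linked variation, not the core's mere existence.

### 1.4 Variance and standardization

For a linear SFS statistic β = ω·ξ (β(1), β(1)\*, and the θ̂_β part of
β(2)), the neutral variance decomposes as

    Var[β] = θ · Σ_k ω_k²/k  +  θ² · ωᵀ Σ ω ,

where Σ is the covariance structure of the SFS. Two models are provided:

- **`coalescent`** (default): Σ is the classical second-moment matrix of
  the neutral, non-recombining coalescent (Fu 1995). This is the honest
  model for windows short enough that sites share one genealogy, and it is
  validated against coalescent simulation (see §4).
- **`poisson`**: Σ = 0, i.e. sites independent, ξ_k ~ Poisson(θ/k). This is
  the matching model for the package's own synthetic generator (§3) and a
  reasonable approximation for very long windows with free recombination.

For β(2), *D* is modelled Poisson(θC) and independent of the polymorphism,
so Var[θ̂_D] = θ/C and

    Var[β(2)] = Var[θ̂_β] + θ/C .

The independence (zero covariance) is a deliberate modelling choice: it
matches the Poisson generator exactly and is conservative in the direction
of not inventing a covariance we cannot compute in closed form. Its
consequence for power comparisons is discussed in §3.3.

The reported score is β_std = β / √Var[β] — scaled, not centred, since the
neutral mean is already 0. Folded weights use w(min(k, n−k)/n) applied to
unfolded classes, so the same machinery covers β(1)\*.

### 1.5 Nuisance parameters

- θ per bp is estimated, when not supplied, as Watterson's estimator over
  all polymorphic input sites divided by the spanned length; the per-window
  θ is then θ_bp × window width.
- *C* is estimated, when *T* and *Nₑ* are not supplied, by the method-of-
  moments rearrangement Ĉ = D_total / θ̂_W,total over the whole input,
  which is consistent because E[D] = θC and E[θ̂_W] = θ region-wide under
  neutrality. Estimation requires both site classes to be present;
  otherwise the package asks for *T* and *Nₑ* explicitly. On a simulated
  neutral genome of ≥10⁴ sites this recovers *C* to within a few percent
  (asserted at 5% in the acceptance tests).

## 2. Parameters, defaults, rationale

| parameter | default | units | rationale |
|---|---|---|---|
| `window` | 1000 | bp | With θ_bp in the 10⁻³–10⁻² range a 1 kb window holds enough SNPs (tens) for a stable θ̂_β while staying within the narrow footprint that tight linkage to a balanced site produces. |
| `p` | 2.0 | — | Sharpness of the similarity kernel. *p* = 2 discounts far frequencies strongly enough to isolate the clustered class without collapsing the weight onto the single exact class; small integer powers also keep the closed-form variance well conditioned. |
| `min_core_freq` | 0.05 | folded frequency | Very rare cores cannot carry a balanced-polymorphism signal and produce noisy, near-degenerate weights; 5% folded frequency removes them. The filter is folded even for unfolded statistics, so cores at frequency 0.96 (folded 0.04) are also skipped. |
| `x` (core frequency) | the core SNP's own frequency; in locus mode the modal SNP frequency of the interval | — | The equilibrium frequency is unknown a priori; the core's frequency is its natural estimate. Calibration studies in this package use *x* = 0.5, the canonical heterozygote-advantage equilibrium. |
| `variance_model` | `coalescent` | — | Real windows share genealogy; the zero-recombination coalescent is the conservative (larger-variance) end, so standardized scores are not overstated. |
| `theta`, `C` | estimated from the input | per bp; dimensionless | See §1.5. |
| generator defaults (`theta_bp` 0.006, `span` 1000, `n` 50, `C` 12, `class_frac` 0.8, `sub_deficit` 0.2) | — | — | Package-chosen study conditions of a realistic vertebrate-scale scan: θ_bp = 0.006 gives E[S] ≈ 27 per kb at n = 50; C = 12 corresponds to, e.g., T/(2Nₑ) ≈ 12 (a distant outgroup); the balanced-fixture knobs produce a strong but not caricatured footprint (80% of SNPs trapped in the allelic class, substitutions reduced to 20%). |

Percentiles, when requested, are midrank empirical percentiles of β_std
within the scan output (ties get the average rank), so the column is a
monotone transform of β_std in (0, 1].

## 3. Synthetic generators

### 3.1 `gen_neutral`

Independent-sites Poisson model for one window: S ~ Poisson(θ a_n),
frequency classes drawn with probability ∝ 1/k, D ~ Poisson(θC), positions
uniform without replacement over the span. This matches the `poisson`
variance model *exactly*, which makes it a clean oracle for the format,
scan plumbing, and the Poisson branch of the variance code.

### 3.2 `gen_balanced`

Same skeleton with three modifications that emulate the balanced footprint:
a core SNP at round(x_eq·n)/n in the middle of the span; a fraction
`class_frac` of the remaining SNPs placed in the allelic class — counts
Binomial(n, x_eq) conditioned on polymorphism (or exactly round(x_eq·n)
with `class_noise=False`); and D ~ Poisson(θC·`sub_deficit`).

### 3.3 What the generators do and do not emulate

Emulated: the frequency build-up near the equilibrium frequency and the
substitution deficit — the two signals the statistics are built to detect —
plus realistic site counts and positions.

Not emulated: genealogy. Sites are independent (no linkage disequilibrium,
no shared coalescent tree within a window, no recombination gradient away
from the core), there is no demography, and — importantly — *D* is drawn
independently of the polymorphism. In real data (and in forward or
coalescent simulation) *D* and S share the same genealogy, so θ̂_D and θ̂_W
are positively correlated and the contrast β(2) cancels genealogical noise.
Under the independent-D generator that cancellation is absent: θ̂_D only
*adds* noise to β(2). The measurable consequence, reported by
`scripts/acceptance.py` and asserted honestly in the acceptance tests, is
that on these fixtures β(2)'s partial AUC does not dominate β(1)'s (they
are within ~2% of each other, with β(1) marginally ahead), even though
β(2)'s sign and calibration behave exactly as designed. This is a property
of the generator's independence assumption, not of the statistics.

### 3.4 Coalescent oracle

For variance validation the package simulates genuine coalescent windows
with `msprime`: haploid samples, population size 1 (so pairwise coalescence
rate 1 and E[branch length of class k] = 2/k), branch-mode SFS, and
ξ_k ~ Poisson((θ/2)·L_k) given the branch lengths L_k. `msprime` is used
only as an oracle and for the `coalescent` window sampler — never inside
the estimators or variances, which are closed-form.

## 4. Validation summary

All claims below are computed by `tests/test_acceptance.py` (with fixed,
pre-registered seeds) and re-computed from a user seed by
`scripts/acceptance.py`; none are hand-asserted.

- Neutral calibration: over 10,000 coalescent windows (n = 50, θ = 6,
  C = 12) the mean of each raw statistic is within 3 standard errors of 0
  and the variance of each standardized statistic lies in [0.9, 1.1].
- Variance equivalence: over the full grid n ∈ {4, 10, 50}, x ∈ {0.1, 0.25,
  0.5}, θ ∈ {1, 5, 20}, C ∈ {5, 12} (108 points, 10,000 replicates each)
  the closed-form variance agrees with simulation within 5% at the test's
  fixed seed. Note the bound is tight relative to Monte-Carlo noise on a
  maximum over 108 points: at other seeds the worst point can exceed 5%
  slightly (the acceptance script reports the actual worst error for the
  seed given).
- Power fixtures: β(2) > 0 in >95% of balanced windows; under a mixture of
  mutation rates (θ and θ/2), standardizing at the generating rate does not
  lose partial AUC relative to the raw statistic. The β(2)-versus-β(1)
  partial-AUC ordering is discussed in §3.3.
- Divergence recovery and worked estimator arithmetic as described above.

## 5. Numerical conventions and degenerate inputs

- Windows are half-open, [pos − w/2, pos + w/2), located with binary search;
  the core SNP is excluded from its own window. A global shift of all
  positions leaves every score unchanged.
- Locus mode scores the interval [start, end) as one window at position
  (start + end)/2; the default core frequency is the interval's modal SNP
  frequency, ties broken toward 0.5 and then toward the smaller frequency.
- The Fu second-moment matrix is computed once per *n* and cached; variance
  lookups in a scan are cached on (statistic, x, p, folded, θ, n, C, model)
  since cores at the same frequency share a variance. An internal identity
  (Σ_ij σ_ij equals the known variance constant of S) guards the matrix.
- Weights are evaluated vectorised with clipping at 0; frequencies outside
  [0, m] are rejected.
- `theta_beta_from_spectrum` accepts fractional spectra so branch-mode
  (expected-SFS) inputs work in the oracles.
- Degenerate inputs raise typed, line-numbered errors rather than returning
  NaN: non-increasing positions, counts outside [1, n], folded counts above
  n/2, substitutions in folded input, empty loci, loci without SNPs, θ
  estimation without polymorphic sites, C estimation without both site
  classes, windows where every weight is ~0. The CLI maps all of these to
  exit status 2 with a message on standard error.
- Scores are written with 6 significant digits; round-tripping a score file
  preserves values to that precision, and site files round-trip exactly.

## 6. Limitations

- The variance models bracket reality (zero recombination vs. free
  recombination) but neither matches an intermediate recombination rate;
  standardized scores are calibrated, not exact, for real windows.
- Var[β(2)] ignores the positive covariance between θ̂_β and θ̂_D that a
  shared genealogy induces, so β(2)_std is slightly conservative on real
  data.
- No demographic corrections: bottlenecks and growth distort the SFS and
  therefore the null calibration; users should standardize against
  empirical genome-wide percentiles (`--percentiles`) in non-equilibrium
  populations.
- Unfolded statistics assume correct ancestral-allele polarisation;
  misidentification moves mass to high frequencies and biases θ̂_β for
  high-frequency cores. β(1)\* avoids this at some cost in power.
- The balanced generator is a caricature for power studies, not a
  population-genetic simulation; absolute power numbers from it should not
  be quoted as expected performance on real data.
- Equilibrium frequency *x* is taken from the data (core or modal
  frequency) rather than jointly estimated; a mis-specified *x* lowers
  power but does not inflate the null.
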