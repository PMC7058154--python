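# betascan2

A genome scan for long-term balancing selection based on the β statistics.

## The problem

Balancing selection (heterozygote advantage, negative frequency-dependent
selection, fluctuating selection) maintains two or more alleles in a
population for a long time. A genomic region linked to such a balanced
polymorphism acquires a recognisable footprint:

1. **an excess of polymorphism** — old genealogies accumulate many mutations;
2. **a cluster of allele frequencies** near the equilibrium frequency of the
   balanced allele, because tightly linked neutral variants become trapped in
   one of the two allelic classes; and
3. **a deficit of substitutions** relative to an outgroup, because lineages
   sampled from the two allelic classes coalesce far in the past, so less of
   the divergence branch is available for fixation.

The β statistics quantify this footprint as a difference between two
estimators of the population-scaled mutation rate θ = 4Nµ, computed in a
window around each putative "core" SNP at frequency *x*:

- **θ̂_β** up-weights variants whose frequency is similar to the core
  frequency, using the weight *w(f) = (1 − |f − x| / m)^p* with *m* = 1 for
  unfolded and *m* = 0.5 for folded frequencies. It is inflated by signal (2).
- **θ̂_W** (Watterson) counts all segregating sites equally.
- **θ̂_D = D / C** converts the substitution count *D* into a θ estimate via
  the divergence scalar *C = T/(2Nₑ) + 1/n*, where *T* is the divergence time
  in generations, *Nₑ* the effective population size and *n* the sample size.
  It is deflated by signal (3).

The three statistics are

| statistic | definition | input needed |
|---|---|---|
| β(1) | θ̂_β − θ̂_W | polarised (ancestral/derived) allele counts |
| β(1)\* | θ̂_β − θ̂_W, folded | minor-allele counts only |
| β(2) | θ̂_β − θ̂_D | polarised counts **and** substitutions vs. an outgroup |

All three have expectation 0 under neutrality and are positive near a
balanced polymorphism. Because their sampling variance depends strongly on
θ, *n* and the core frequency, the package also provides closed-form
variances under the neutral coalescent and reports the standardized score
β_std = β / √Var[β], which is comparable across windows, samples and species.

Intended audience: population geneticists running selection scans on SNP
frequency data, and methods developers who need the estimators, their
variances, and calibrated synthetic data in library form.

## Input format

Whitespace/tab-separated text (optionally gzipped), one variant per line,
positions 1-based and strictly increasing:

```
position  derived_count  sample_size
```

A line with `derived_count == sample_size` is a substitution relative to the
outgroup (used only by β(2)). With `--fold`, counts are minor-allele counts
and substitutions are not representable. A header line whose first field is
not an integer is skipped.

## Quick start

Simulate a 50 kb neutral background, embed a 1 kb window shaped by a
balanced polymorphism at frequency 0.5 in its middle, and scan with β(2)
(the commands below are exactly what produced the output shown):

```sh
betascan2 simulate neutral  --seed 5 --theta-bp 0.006 --span 50000 --n 50 --C 12 -o neutral.txt
betascan2 simulate balanced --seed 6 --theta-bp 0.006 --span 1000  --n 50 --C 12 --x-eq 0.5 -o bal.txt

awk '$1 <= 25000' neutral.txt            >  genome.txt
awk '{print $1 + 25000 "\t" $2 "\t" $3}' bal.txt >> genome.txt
awk '$1 > 26000' neutral.txt             >> genome.txt

betascan2 scan -i genome.txt --B2 --estimate-theta --estimate-divergence -w 1000 -o scores.tsv
```

The scan logs to standard error:

```
[betascan2] INFO: read 4915 sites from genome.txt
[betascan2] INFO: statistic=B2 window=1000 p=2 min_core_freq=0.05; 905 cores scored, 475 filtered
```

and writes one row per eligible core SNP:

```
position	beta	variance	beta_std
3	2.09634	13.0767	0.579713
18	1.80319	6.58903	0.702477
40	1.52594	4.9347	0.68692
...
```

The five highest standardized scores (`sort -k4 -g scores.tsv | tail -5`)
all fall inside the inserted balanced segment [25001, 26000]:

```
25143	7.38997	7.89617	2.62987
25485	6.76139	6.29825	2.69418
25524	8.9286	9.60726	2.8806
25500	8.34595	8.24118	2.90724
25438	8.72237	8.58244	2.97734
```

Other modes:

- `--fold` scores β(1)\* on minor-allele counts; omitting both `--fold` and
  `--B2` scores β(1).
- `betascan2 locus --start A --end B` scores one predefined interval as a
  single window (core frequency defaults to the interval's modal SNP
  frequency).
- `--divergence-time T --Ne NE --n N` computes *C* from first principles
  instead of estimating it from the data; `--theta` fixes θ per bp.
- `--percentiles` appends an empirical percentile column; `--config FILE`
  reads `key = value` defaults (explicit flags win).

## Library use

```python
import numpy as np
from betascan2 import WeightSpec, WindowCounts, beta2, variance_beta

win = WindowCounts(freqs=np.array([0.48, 0.52, 0.50, 0.12, 0.90]),
                   D=40, n=50, span=1000)
spec = WeightSpec(x=0.5, p=2.0)
b = beta2(win, spec, C=12.0)                        # -1.4973
v = variance_beta("B2", spec, theta=6.0, n=50, C=12.0)  # 7.8454
print(b / np.sqrt(v))                               # -0.5346
```

Higher-level entry points: `scan`, `score_locus`, `read_sites`,
`write_scores`, the generators `gen_neutral` / `gen_balanced` and the
Monte-Carlo oracle `monte_carlo_variance`. See `docs/methods.md` for the
model, parameter defaults and their rationale, and known limitations.

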