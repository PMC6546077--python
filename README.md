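# longqtl

QTL interval mapping for longitudinal (function-valued) traits in inbred
crosses (BC, F2, RIL, DH).

Each putative QTL genotype's mean trajectory follows a parametric curve
(logistic, double-logistic, Legendre polynomial, pharmacology — user
extensible), residuals follow a structured longitudinal covariance (VC, CS,
AR1, AR1_time, ARMA11, Toeplitz, SAD1 — user extensible), and individuals
enter a multivariate-normal mixture weighted by conditional QTL-genotype
probabilities from the flanking markers (Haldane map function, no
interference).  The genome is scanned at 1 cM resolution with the
LR2 = −2 log-likelihood-ratio statistic between the one-curve null and the
genotype-specific alternative (fitted by a generalized EM), and genome-wide
significance comes from permutation of phenotype rows, optionally restricted
to positions pre-filtered by a genotype-dosage/trait correlation screen.

## Input formats

Four UTF-8, comma-separated CSV files:

| file | schema |
|---|---|
| marker | header `marker,chr,pos_cM`; positions strictly increasing per chromosome |
| genotype | first column `id`, one column per marker id; BC/DH/RIL codes {0,1}, F2 codes {0,1,2} (1 = heterozygote); missing = empty, `NA`, or `-1` |
| phenotype | first column `id`, remaining columns time labels (numeric labels used verbatim, `t1..t11` → 1..11) |
| covariate (optional) | first column `id`, numeric columns |

Individuals are linked case-sensitively by `id`; rows present in only one
file are dropped with a warning.

## CLI

```sh
# simulate a test dataset (CSV files + truth.json sidecar)
longqtl simulate --n 200 --n-chrom 5 --n-markers 12 --qtl-chrom c1 --qtl-pos 34 --out simdata

# full pipeline: load -> auto model selection -> scan -> permutation -> report
longqtl pipeline --pheno simdata/pheno.csv --geno simdata/geno.csv \
    --marker simdata/marker.csv --cross BC \
    --curve auto --covariance auto --step-cm 1 \
    --n-perm 200 --alpha 0.05 --workers 4 --seed 1 --out results/

# individual steps
longqtl scan ... ; longqtl permute ... ; longqtl report ...
```

`--curve auto` selects among registered curves by least-squares AIC/BIC;
`--covariance auto` selects by maximum likelihood + AIC.  Outputs are CSVs
(scan profile, per-chromosome peaks, permutation maxima), PNG plots
(trait trajectories, LR2 profiles with marker labels and threshold line,
genotype-specific curves for significant QTLs), and a `manifest.json`
recording configuration, seeds and versions; reruns with the same
configuration are byte-identical.  Exit codes: 0 ok, 2 input error,
3 convergence error.

## Library

```python
import numpy as np
from longqtl import (load_dataset, qtl_scan, permute_scan, find_peaks)

ds = load_dataset("pheno.csv", None, "geno.csv", "marker.csv", "BC")
sr = qtl_scan(ds, "logistic", "AR1", step=1.0)
pr = permute_scan(ds, "logistic", "AR1", n_perm=1000, seed=1)
print(find_peaks(sr), pr.threshold(0.05))
```

New trajectory families / covariance structures plug in via
`longqtl.register_curve` / `longqtl.register_covariance`.

## Documented modeling choices

- Haldane map function (no interference); RIL means selfed RIL (F∞) with the
  per-interval expansion r* = 2r/(1+2r).
- Missing flanking genotypes fall back to population-expectation priors
  (BC/DH/RIL ½,½; F2 ¼,½,¼); missing phenotype cells are marginalized out of
  the MVN rather than dropping the row.
- `AR1` uses index distance between measurements; `AR1_time` uses calendar
  time.
- Covariate effects are time-constant scalar shifts.
- The permutation pre-filter is a dosage–trait correlation screen that
  always retains each chromosome's observed peak.
- Thresholds are type-7 empirical quantiles; default α = 0.05.
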