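# trimlogit

Robust elastic-net logistic regression for mislabeled high-dimensional data.

`trimlogit` fits a **trimmed** penalized logistic model: instead of using all
n samples, it searches for the size-h subset (h = ⌊ηn⌋, default η = 0.75)
that minimizes the penalized negative log-likelihood, so that mislabeled
samples — e.g. misdiagnosed patients in an omics cohort — are excluded from
the fit rather than allowed to distort it.  A reweighting step then flags
suspect samples by the Pearson residuals of the robust fit and refits on the
cleaned sample set.

The subset search combines classic concentration steps (fit on a subset,
rank all samples by deviance, re-form the subset from the best-fitting h)
with a Metropolis-type acceptance–rejection rule that tolerates the
criterion fluctuations caused by re-selecting the regularization parameters
(λ, α) by cross-validation at every step, while always tracking the best
subset seen.  A plain fixed-parameter concentration search and a full-grid
variant are included as baselines, plus an exhaustive oracle for testing.

## Layout

| module | contents |
|---|---|
| `trimlogit.core` | labeled-matrix container, subset standardization, the coordinate-descent elastic-net logistic solver, deviances, λ/α grids, CV selection |
| `trimlogit.trimming` | trimming plans (h, h1, h0), the criterion Q, stratified candidate subsets |
| `trimlogit.search` | fixed-parameter C-steps, grid C-steps, the acceptance–rejection search, multi-start driver, exhaustive oracle |
| `trimlogit.reweight` | refits, Pearson-residual outlier flagging, the end-to-end `run_mtl_en` pipeline |
| `trimlogit.synthdata` | seeded generator of sparse logistic datasets with label-flip contamination |
| `trimlogit.metrics` | Sn / FPR (outlier detection) and PSR / FDR / GM (variable selection) |
| `trimlogit.cli` | CSV/TSV IO and the `trimlogit` command line |

## Command line

```sh
# make a contaminated synthetic fixture (CSV + ground-truth JSON)
trimlogit simulate --n 200 --p 400 --epsilon 0.1 --seed 1 --out scratch/sim

# robust fit; writes coefficients.json, outliers.tsv, trace.jsonl, config.json
trimlogit fit scratch/sim.csv --seed 1 --out-dir scratch/fit_out

# score the fit against the ground truth
trimlogit evaluate scratch/fit_out/coefficients.json scratch/sim.truth.json

# exhaustive baseline (tiny inputs only)
trimlogit oracle scratch/tiny.csv
```

Input format: delimited text, samples in rows, first column sample id, a 0/1
`label` column (`--label-col` to rename), remaining columns numeric features;
`--transpose` accepts the features-in-rows dialect.

## Python API

```python
import numpy as np
from trimlogit import ARCstepConfig, run_mtl_en
from trimlogit.synthdata import SyntheticSpec, generate

ds = generate(SyntheticSpec(n=200, p=400, q=10, epsilon=0.1, seed=1))
fit = run_mtl_en(ds.data, eta=0.75, cfg=ARCstepConfig(seed=1))
print(fit.report.flagged_ids)        # suspected mislabeled samples
print(fit.selected_features)         # nonzero features of the reweighted fit
```

## Notes on defaults

* The outlier cutoff is `|Pearson residual| > 1.0`, i.e. a sample is flagged
  when its label contradicts the fitted probability (wrong side of 1/2).
  The classical 2.5σ rule is available via `--cutoff`, but with CV-shrunk
  sparse fits it flags almost nothing.
* The warm phase evaluates all starts at a single heavy-shrinkage
  λ (= 0.5·λ_max, α = 0.5) so their criterion values are comparable; CV
  re-selection of (λ, α) begins in the convergence phase.
* Known limitation: with many quasi-independent features (p ≫ h, low
  feature correlation) the elemental 6-sample warm starts carry little
  ranking information and concentration steps cannot expel mislabeled
  samples that the subset model has already absorbed, so detection
  sensitivity degrades.  See `tests/test_acceptance.py::test_c6_*`.
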