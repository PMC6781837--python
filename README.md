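# gwpred

Penalized whole-genome regression with honest model-comparison statistics.

## The problem

Genome-wide prediction regresses a quantitative phenotype on thousands of
SNP markers (coded 0/1/2), almost always with more markers than
individuals, so regularized estimators — ridge regression (RR), the LASSO
and the adaptive LASSO (ALASSO) — are tuned on hold-out test data. Three
statistics compete in practice for deciding which model "won":

- **test MSE** = (1/n)Σ(yᵢ − ŷᵢ)², the prediction loss itself;
- **r²** = COV[y,ŷ]² / (VAR[y]·VAR[ŷ]), the squared Pearson correlation,
  quantitative genetics' customary "accuracy";
- **R²** = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)², the coefficient of determination.

For a fixed test set, R² is a monotone transform of MSE, so the two always
agree. r² is different: it is invariant to affine maps of the predictions
(a·ŷ + b scores exactly like ŷ), so a model whose predictions are
systematically shrunk — which is what regularization does — loses nothing
under r² while its MSE deteriorates. Because the three estimators shrink by
different amounts (VAR[ŷ] differs strongly between RR, LASSO and ALASSO
while VAR[y] is fixed), r² can crown a different winner than MSE and R²,
and with it a different ranking of candidate individuals. `gwpred` makes
this failure mode measurable: it fits all three methods over a
regularization path, scores every statistic, decomposes r² into its
COV/VAR parts, and reports where the criteria disagree.

The package is aimed at quantitative geneticists and statisticians who
benchmark genomic-prediction models and want the comparison machinery —
solvers, metrics, selection, ranking, and a fully synthetic test bed — in
one reproducible toolchain.

## What's inside

- `data_io` — delimited genotype/phenotype readers and writers (plus a
  zip-archive loader and a PLINK-raw-like dialect), MAF filtering,
  column standardization, fixed and K-fold splits.
- `solvers` — OLS, ridge (primal and dual form for p > n), GBLUP on
  G = XXᵀ, LASSO/ALASSO by numba-accelerated cyclic coordinate descent,
  λ grids and warm-started paths.
- `evaluation` — MSE, r², R², the COV/VAR decomposition, a Cp-style
  unbiased-risk criterion for ridge, per-criterion model selection,
  top-k individual ranking and rank-agreement measures (Spearman,
  Kendall, top-k overlap), CSV table writers.
- `simulate` — a QTLMAS2010-style generator: 5-generation pedigree, gene
  dropping from a finite founder-haplotype pool (LD decays with map
  distance), 37 QTLs (additive majors and minors, maternal imprinting,
  marginally silent epistatic pairs) plus dominance/over-/under-dominance
  loci, with the residual variance calibrated to a narrow-sense
  heritability of 0.45.
- `pipeline` / `gwpred` CLI — the whole experiment from a JSON config,
  with deterministic, provenance-stamped CSV reports.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

Simulate a 500-individual, 1,000-marker population, train on the first 350
individuals, and compare the three methods over a 20-value path:

```python
import gwpred as gw

sim = gw.SimConfig(
    generation_sizes=(60, 140, 140, 160),   # 500 individuals, 4 generations
    n_markers=1000, n_chromosomes=5, founder_haplotype_pool=12, seed=7,
)
cfg = gw.ExperimentConfig(sim=sim, maf=0.01, train_last=350,
                          n_lambda=20, seed=7)
res = gw.run_experiment(cfg)
for method, rep in res.table1.items():
    print(method, {k: round(v, 3) for k, v in rep.as_dict().items()})
print(gw.compare_criteria(res)["winners"])
```

Output:

```
RR     {'MSE': 23.013, 'r2': 0.258, 'R2': 0.246, 'COV': 8.972, 'VAR_yhat': 10.199, 'VAR_y': 30.541}
LASSO  {'MSE': 22.076, 'r2': 0.290, 'R2': 0.277, 'COV': 6.911, 'VAR_yhat': 5.389, 'VAR_y': 30.541}
ALASSO {'MSE': 21.800, 'r2': 0.295, 'R2': 0.286, 'COV': 8.934, 'VAR_yhat': 8.849, 'VAR_y': 30.541}
{'min_mse': 'ALASSO', 'max_r2': 'ALASSO', 'max_R2': 'ALASSO'}
```

Reading it: the adaptive LASSO has the lowest test MSE and the highest R²
and r² here, so the criteria happen to agree on this draw — but the
decomposition shows why they need not. VAR[y] = 30.5 is common to all
rows, while VAR[ŷ] ranges from 5.4 (LASSO, strongest shrinkage) to 10.2
(ridge): r² only sees the *ratio* structure of COV and VAR[ŷ] and is blind
to the absolute shrinkage that MSE penalizes. The `ranking_overlap` entry
of `compare_criteria` shows that even here, LASSO's top-10 individuals
change (overlap 0.8) depending on whether the penalty is chosen by MSE or
by r². On the benchmark-scale dataset this package targets, the
disagreement is complete: r² prefers the LASSO while MSE and R² prefer the
adaptive LASSO.

The same experiment runs from the shell:

```bash
gwpred simulate --config sim.json --out simdir/
gwpred run --config experiment.json --out results/
gwpred report --in results/
```

With a local copy of the QTLMAS2010 benchmark archive
(`QTLMAS2010ny012.zip`, from github.com/patwa67/AUTALASSO) placed in
`data/`, the deposited-data experiment is
`gwpred run` with `"zip_path": "data/QTLMAS2010ny012.zip"`, `"maf": 0.01`,
`"train_last": 2326`, `"n_lambda": 100`; the MAF filter then retains 9,723
SNPs and the acceptance test
(`tests/test_acceptance.py::TestDepositedDataReproduction`) checks the
published comparison table.

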