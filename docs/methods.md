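# Methods

## Problem setting

`gwpred` addresses model comparison in genome-wide prediction: given SNP
genotypes coded 0/1/2 for n individuals at p markers (typically p > n) and a
continuous phenotype, penalized regressions are tuned on a hold-out test set
and then compared across methods. The package exists to make one
statistical point reproducible end to end: the squared Pearson correlation
r², widely used in quantitative genetics as a standardized "accuracy", is
invariant to affine distortion of the predictions, so it can crown a
different winning model than the test mean squared error (MSE) or the
coefficient of determination R². The honest loss is the test MSE; R² is its
standardized monotone transform; r² is not.

## Models

All solvers work on a column-standardized design X (population convention:
each column has mean 0 and variance 1, so xⱼᵀxⱼ = n exactly) and a centered
response y; no intercept is fitted anywhere.

* **OLS** solves the normal equations XᵀXβ = Xᵀy via an SVD-backed least
  squares solve, gated at condition number 1e12, and requires n ≥ p.
  Its residual variance σ̂²ₑ = RSS/(n − p) feeds the ridge Cp criterion.
* **Ridge** β̂ = (XᵀX + λIₚ)⁻¹Xᵀy; for p > n the dual identity
  β̂ = Xᵀ(XXᵀ + λIₙ)⁻¹y is used (an n×n solve instead of p×p). The two
  routes solve the same equations and agree to 1e-8 in the tests.
* **GBLUP** predicts genetic values ĝ = G(G + λIₙ)⁻¹y with G = XXᵀ; this
  is random-effects ridge with λ = σ²ₑ/σ²_g and equals the ridge
  predictions Xβ̂ exactly, which the suite asserts.
* **LASSO / adaptive LASSO** minimize
  (1/(2n))‖y − Xβ‖² + λ Σⱼ wⱼ|βⱼ| by cyclic coordinate descent with
  soft-thresholding (wⱼ = 1 for the plain LASSO). The 1/(2n) loss scaling
  keeps λ grids comparable across sample sizes; a penalty stated without it
  corresponds to λ_internal = λ_unscaled/(2n).

### Adaptive weights

Weights come from marginal covariances cⱼ = |xⱼᵀy|/n. The default mode is
`inverse`, wⱼ = 1/(cⱼ + ε) with ε = 1e-8·max c: markers with strong marginal
association are shrunk less, which is the purpose of the adaptive variant
(reducing the shrinkage bias of the plain LASSO at the cost of some
variance). A `literal` mode with wⱼ = cⱼ + ε is retained for sensitivity
analysis; it penalizes strong markers hardest and is not the default
because it inverts the adaptive rationale.

### Paths and tuning

The penalty grid is log-spaced over 100 values from
λ_max = maxⱼ |xⱼᵀy|/(n·wⱼ) — the smallest penalty with an all-zero
solution — down to λ_max·min_ratio (0.01 for p > n, 1e-4 otherwise).
Coordinate descent is warm-started along the grid; warm and cold fits agree
to 1e-6 in the tests. Convergence tolerance is 1e-7 on the largest
coefficient change per sweep, with a 10,000-sweep cap that warns rather
than raises. Ridge fits along the same grid use the matrix-scale penalty
nλ, the exact minimizer of the shared 1/(2n)-scaled objective with an
ℓ2 penalty, so all three methods live on one λ scale. For ridge without a
test set, a Cp-style unbiased-risk criterion is provided:
RSS(λ) − nσ̂²ₑ + 2σ̂²ₑ·df(λ) with df(λ) = tr[XᵀX(XᵀX + λI)⁻¹] computed from
the eigenvalues of XᵀX. (The chain RSS − nσ² = σ²tr[...] sometimes quoted
for this criterion is not a usable identity — its two sides have different
λ limits — so the standard unbiased-risk form is implemented, with the
trace as the effective degrees of freedom.)

## Evaluation statistics

On a test split (y, ŷ), with population (divide-by-n) moments:

* MSE = (1/n)Σ(yᵢ − ŷᵢ)²
* r² = COV[y,ŷ]² / (VAR[y]·VAR[ŷ]); affine-invariant in ŷ; a constant
  predictor is scored 0 with a warning
* R² = 1 − Σ(yᵢ − ŷᵢ)²/Σ(yᵢ − ȳ)², where ȳ is the mean of the supplied
  test responses (a training-mean variant is a one-flag change); may be
  negative

`decompose` reports all of these plus COV[y,ŷ], VAR[y], VAR[ŷ]. r² is
invariant to the population/sample moment convention, but the COV/VAR
cells are not, so the table writer can emit either (sample cells are the
population ones times n/(n−1)).

Within one path on a fixed test set, argmin MSE = argmax R² (identity);
the pipeline asserts it on every run. Model-selection ties break toward
larger λ (parsimony). In the method-comparison table each statistic is
reported at its own path-optimal λ — that is what "smallest test MSE and
largest test r²" selection means operationally — so the COV/VAR
decomposition belongs to the r²-optimal fit while MSE and R² share the
MSE-optimal one.

## Synthetic data

The generator emulates the structure of the QTLMAS2010 workshop dataset as
used in genomic-prediction benchmarks, at the same scale:

* **Pedigree**: 3,226 individuals in 5 generations (100 founders, then
  626/800/800/900), random mating of parents drawn from the previous
  generation, no selfing, full-sib families of 2 by default.
* **Genotypes**: 10,000 SNPs on 10 chromosomes of 1 Morgan. Founder
  haplotypes are drawn from a pool of 20 ancestral haplotypes (per-marker
  allele frequencies uniform on 0.1–0.9); gene dropping uses a Haldane
  crossover model, implemented as a per-marker haplotype-switch chance
  r = ½(1 − e^(−2d)) at adjacent-marker distance d, with an independent ½
  draw at each chromosome start. The finite pool induces LD that decays
  with map distance (asserted empirically over 20 replicates).
* **Architecture**: 37 QTLs — 2 additive majors (|effect| 3), 28 minors
  with truncated-normal effects (mean 0, sd 1, bounds ±2), 3 maternally
  imprinted loci (|effect| 2; the maternal copy is silenced, so only the
  paternally inherited allele contributes), 2 epistatic pairs (|effect| 2)
  with no individual effects — plus one dominance (map {0:0, 1:2, 2:2}),
  one over-dominance ({0:0, 1:1.5, 2:0}) and one under-dominance
  ({0:0, 1:−1.5, 2:0}) locus. All 40 loci are distinct markers with
  MAF ≥ 0.05. Effect magnitudes are configuration, not claims about the
  original workshop data: the benchmark describes that dataset's counts,
  classes and h², not its generator's parameters.
* **Epistasis with no marginal effects** is realized exactly on the sample:
  the centered-code products are residualized (least squares) against a
  design holding the codes of every epistatic locus, so the component's
  sample correlation with each constituent locus is zero to machine
  precision — rather than only zero in expectation under
  Hardy–Weinberg assumptions.
* **Heritability calibration**: the residual variance is set per replicate
  to σ²ₑ = Var(A)/h² − Var(G), where A is the additive component (majors +
  minors only) and G the sum of all genetic components, so that
  Var(A)/Var(y) targets h² = 0.45 in the narrow sense. The realized value
  fluctuates with the drawn residuals (sd ≈ 0.01 at n = 3,226); the mean
  over 20 replicates sits within ±0.02 of target, which the acceptance
  suite checks at full scale.

The phenotype is stored together with every component and the residual,
and the decomposition is exact to 1e-12.

What the simulator does **not** reproduce: the original QTLMAS2010 marker
map and LD pattern, selection or non-random mating, sex chromosomes, and
missing genotypes. Passing tests on simulated data therefore demonstrate
correctness of the estimators and the selection logic under a realistic
architecture, not performance claims about any real dataset.

## Pipeline

`run_experiment` chains: load (delimited files, a zip archive, or the
simulator) → MAF filter (keep marker j iff min(fⱼ, 1−fⱼ) ≥ threshold,
fⱼ = mean(code)/2, inclusive boundary; default 0.01) → standardize
(statistics from all rows by default, matching a single-matrix
standardization; training-only statistics are one flag away) → leading-block
split (1-based `train_last`, e.g. 2,326 of 3,226) → per-method λ paths →
per-criterion selection → a method × metric table and a
method/criterion × top-10 ranking table, written as CSV with `#` header
lines carrying the package version, a hash of the scientific configuration
and the seed. `compare_criteria` reports each criterion's winning method,
flags criterion pairs that disagree, and gives the top-10 overlap between
MSE-selected and r²-selected rankings per method. Runs are deterministic
given the configuration; two runs produce byte-identical tables.

## Problem sizes used in the tests

Unit tests use designs of tens of rows and columns, a small simulated
population (300 individuals, 400 markers, 4 generations) shared across
simulator tests, and a 500 × 1,000 end-to-end smoke experiment with a
20-value path. The acceptance checks run the simulator at the full default
scale (3,226 × 10,000, 20 replicates). The deposited-data reproduction test
requires `data/QTLMAS2010ny012.zip` to be present locally and fails with a
pointer to the source repository otherwise.

## Known limitations

* Coordinate descent is plain cyclic (no active-set or strong-rule
  screening); determinism and verifiability were preferred over speed. The
  numba-compiled kernel handles the study-scale problem comfortably.
* The adaptive-weight ε guard makes weights for markers orthogonal to y
  finite but enormous; such markers are effectively excluded, which is the
  intended behavior.
* `cp_variant` selection applies to ridge only and needs an n > p
  sub-problem (or an external σ̂²ₑ); it is not part of the default
  criterion set.
* The evaluation protocol tunes and reports on the same hold-out split, as
  hold-out benchmarks in this literature do; a third validation split or
  K-fold cross-validation is supported by the utilities but is not the
  default protocol.
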