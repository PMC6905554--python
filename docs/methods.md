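# Methods

## One-class model

The core model is the ν-parameterized one-class SVM: separate the training
class from the origin in the kernel feature space with maximum margin.
The package solves the dual

    minimize ½ αᵀKα   s.t.  0 ≤ αᵢ ≤ 1/(νl),  Σαᵢ = 1

with an SMO-style solver: at each step the maximal-violating pair of the
gradient g = Kα is selected (the coordinate best able to grow against the
one worst able to shrink) and mass is transferred between the two by the
exact one-dimensional Newton step clipped to the box. Because the feasible
set carries unit mass, the maximal violation bounds the duality gap, and
iteration stops at gap ≤ 1e−8. The offset ρ is the mean of g over margin
support vectors (0 < αᵢ < 1/(νl) strictly, beyond a support-vector
tolerance of 1e−7·max α); when no strictly interior α exists the KKT
conditions only bracket ρ between max g over bound points and min g over
zero points, and the midpoint of that interval is used — any value in it
is optimal, the midpoint is deterministic. Slack values are recovered as
ξᵢ = max(0, ρ − gᵢ).

A score of exactly zero is classified inlier: the decision rule is
"non-negative ⇒ member of the trained class".

SVDD (minimum enclosing hypersphere, box constraint C ≥ 1/l) reuses the
same solver on min αᵀ(2K)α − diag(K)ᵀα. R² is the squared kernel distance
from the implied center to the margin support vectors (averaged); a
single-point fit degenerates to R² = 0. For kernels with constant diagonal
(RBF) and C = 1/(νl) the two duals differ by a constant, so the SVDD score
is exactly twice the OCSVM score and labels coincide — the package asserts
≥ 99% grid agreement in tests and routinely measures 100%.

Numerical choices: training-outlier counts in the ν-property checks use a
score threshold of −1e−6, one hundred times the solver's 1e−8 gap, so
margin support vectors carrying O(gap) score noise are not miscounted as
outliers. An independent multi-start SLSQP route (`qp_oracle`, capped at
12 variables) validates the solver's objective to 1e−6 in tests; the SMO
solver, not the oracle, is always the production path.

Defaults: ν = 0.05 (reject at most 5% of training positives — a
conservative novelty-detection setting; the benchmark study this package
replicates does not report its value, so it is exposed as configuration),
RBF γ = 1/d with d the feature count (the common inverse-dimension
heuristic; also unreported upstream, also exposed).

## PU evaluation

With positives and unlabeled genes only, the confusion matrix yields just
TP and FN, so recall r is directly estimable on held-out known positives.
Precision p = P[Y=1 | f(x)=1] is recovered by Bayes inversion,
p = r·P[Y=1]/P[f(x)=1], with P[f(x)=1] the positive-prediction rate over
the full validation pool and P[Y=1] the fraction of known positives in
that pool. This is the only estimator constructible from the three
quantities the scheme defines, and it makes p = r an algebraic identity
whenever the prediction rate equals the prior — which is why a one-class
model that accepts positives and rejects (almost) everything else reports
identical precision and recall columns. Estimates above 1, possible
through sampling noise, are clipped to 1 and logged. A model-selection
criterion r²/P[f(x)=1] (proportional to p·r) is also computed. A "naive"
mode that counts unlabeled validation genes as negatives is provided for
comparison with binary-classifier conventions; PU mode is the default.

## Benchmark construction

Differential expression uses Welch's two-sample t-test per gene on log₂
values (assumption-light with unequal group variances) with
Benjamini–Hochberg adjustment across all genes; log₂ fold change is the
disease-minus-healthy difference of mean log₂ expression. Inputs are
assumed log-scale already (preprocessed microarray convention); a flag
applies log₂(x+1) otherwise. Positives require |logFC| > 1 **and**
adjusted p < 0.05, both strict, so boundary values are unlabeled. All
non-positives are unlabeled; an optional cap keeps only the genes with
smallest |logFC| to mimic fixed-size unlabeled pools.

Outlier removal (before training, positives only) drops genes whose
robust z-score — (x − median)/(1.4826·MAD) per feature — exceeds 4 in
absolute value on any feature; MAD = 0 features are skipped. The method
and threshold are configurable since no canonical choice exists for this
step.

Min-max scaling to [0,1] is fitted on the training matrix only and reused
(with clipping) on test data, avoiding test-set leakage; a `--scale-all`
switch fits on all feature vectors for compatibility with global-scaling
protocols. Constant features map to 0.

The 70/30 positive split is seed-reproducible; unlabeled genes never enter
training. Cross-validation partitions training positives into k seeded
folds and reports held-out recall, the only classical metric computable
within a positives-only pool.

## Synthetic data: what it emulates and what it does not

The generator emulates a preprocessed two-condition microarray benchmark:
per-gene baseline means uniform on [4, 10] log₂ units, i.i.d. gaussian
noise (SD 1.0) across samples — the simplest model consistent with the
t-test machinery — and planted disease genes shifted by δ = 3 noise-SDs in
the disease samples with a random sign per gene, matching the two-sided
|logFC| rule. Defaults (2500 genes, 47% planted, 26 disease + 38 healthy
samples, 10% of planted genes withheld from the positive label as hidden
contamination) mirror the shape of the AML benchmark the pipeline targets:
1174 positives and 1300 unlabeled genes over 64 samples.

What it deliberately does not model: probe-level artifacts, batch effects,
and gene–gene correlation. One structural consequence matters for
interpreting test results: with random shift signs, a flat null profile
equals a 50/50 mixture of an up-shifted and a down-shifted positive
profile, so null genes lie **inside the convex hull of the positive
class**. No single convex one-class boundary (linear, or RBF at the
smooth default γ) can reject them, so on synthetic data the one-class
model shows textbook recall (≈ 1 − ν) but PU precision near the class
prior. Passing tests therefore demonstrate solver correctness, estimator
calibration, protocol integrity and the recall behaviour — not that
synthetic unlabeled genes are separable from positives. On real
benchmarks, where strongly differential genes occupy their own region of
expression space and the unlabeled pool another, the same pipeline can
produce the near-equal precision/recall pattern characteristic of
published one-class results; reproducing those exact numbers requires the
original expression files, which are not redistributable here, plus
hyperparameters (ν, γ, seeds, outlier method) their source does not
report.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the full
cycle completes in seconds while every statistical check retains power:
solver-vs-oracle agreement on 50 random QPs with l ≤ 10; the ν-property at
l = 200 over 4 ν values × 20 seeds; OCSVM/SVDD agreement on 20 fits × a
400-point grid; estimator recovery at 5000 validation genes × 20 seeds;
type-I/power at 2000 genes with 30+30 samples; the shaped-benchmark
experiment at the full 2474 × 64 size over 10 splits.

## Known limitations

- Only linear and RBF kernels; no online updates.
- The SMO solver is exact but dense (O(l²) memory in the Gram matrix);
  it is intended for benchmark-scale l (thousands), not genome-scale
  training sets.
- The Bayes-inverted precision assumes the held-out positives are an
  unbiased sample of all positives in the pool; selection bias in how
  positives were confirmed violates this silently.
- Baseline hyperparameters (RBF-SVM C = 1, k = 5, unlimited-depth tree)
  are protocol defaults, recorded in reports, not tuned reproductions of
  any published configuration.
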