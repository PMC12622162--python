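# Methods

`fevep` implements a functional-evidence framework for missense variant
interpretation: it builds balanced training sets from heterogeneous functional
and clinical label sources, trains gradient-boosted classifiers under strict
circularity controls, calibrates the resulting scores into ACMG/AMP PP3/BP4
evidence strengths, and propagates classified variants into gene-level genetic
epidemiology. This note records the models, the tunable parameters and their
defaults, the numerical choices, and what the synthetic test bed does and does
not demonstrate.

## Dataset construction

**Assay calibration.** A multiplexed functional assay reports one continuous
score per variant for one gene, with unknown orientation. Calibration against
binary clinical labels on the overlapping variants (a) resolves orientation by
flipping scores whenever the rank AUC is below 0.5, (b) tests separation with
a one-sided Mann–Whitney rank-sum test, and (c) accepts the study when
p ≤ alpha / n_studies (Bonferroni across the studies screened) and the
labeled overlap has at least `min_overlap` (default 10) variants. Everything
is rank-based, so any strictly monotone rescaling of assay scores leaves the
decision unchanged. Accepted studies are binarized at the cut that maximizes
balanced accuracy on the labeled overlap; tying cuts resolve to their
midpoint.

**Source merging.** Functional sources merge with precedence
curated > assay-derived > text-mined: a variant takes its label from the
highest-precedence source that contains it, and variants with conflicting
labels inside one precedence level are dropped rather than voted, keeping
labels high-confidence. Proxy-benign population variants are admitted only
where no labeled source covers the key, are always labeled neutral, and carry
a sample weight equal to their min–max-normalized log10 allele frequency
(all-equal inputs degenerate to weight 1). Log base 10 is a presentation
choice; any base gives identical weights after min–max normalization.

**Clinical set.** Archive rows are kept at review status ≥ 2 stars with a
conclusive pathogenic / likely pathogenic / benign / likely benign assertion,
collapsed to binary. Variants with a splice-disruption score strictly above
0.2 are removed so that the missense consequence, not cryptic splicing, is the
signal being labeled; variants lacking a splice score are retained.

**Per-gene balancing.** Within each gene carrying both classes, the majority
class is down-sampled uniformly (seeded) to the minority count, so well-studied
genes cannot dominate the loss and per-gene label priors are flat. Genes with
a single class are dropped by default; the `keep_capped` policy instead
retains them capped at the median balanced-class size, for corpora where
single-class genes carry real signal.

## Circularity control

Each predictor score in the feature matrix is linked to a registry entry
listing the tool's training variants and its component tools (for
meta-predictors). The effective training set of a tool is the union of
training sets over all tools reachable in the component graph (validated
acyclic at load). Any cell pairing a variant with a predictor trained on it is
set to missing before training or benchmarking; non-predictor features are
never touched, and masking is idempotent. Masked cells become ordinary
missing values and are eligible for imputation downstream: the framework
imputes informative missingness after omission rather than leaving holes whose
pattern encodes the label. Tools with unknown training data can be flagged
`training_unknown`; they are retained as model features but should be excluded
from benchmark comparisons.

## Features

Four protein-language-model metrics summarize how a substitution perturbs
sequence plausibility: mean log-likelihood difference (wild-type − mutant,
natural log), perplexity difference (mutant − wild-type, perplexity =
exp(−mean log-likelihood)), Euclidean shift of the mean embedding, and the
site-local log-likelihood difference at the mutated position. Signs are fixed
so larger values indicate damage; the three difference metrics are
antisymmetric under swapping wild-type and mutant, the embedding shift is
symmetric. Statistics come from a provider interface (deterministic per
sequence), so any language model — or a synthetic stand-in — can back them.

**Informative missingness.** A feature whose missingness rate differs between
classes leaks labels through its missing pattern. Features are flagged by a
two-proportion z-test on per-class missingness at alpha = 0.01 (the selection
rule is this package's choice); fully missing features are flagged
unconditionally. Flagged features are filled by LightGBM regressors trained on
unlabeled background variants only (labels never enter), using all other
features as predictors; trees route missing predictor values natively.
Observed cells are never altered, and imputation provenance is recorded.
Regressors are trained once on the full catalog rather than per feature
regime; the regime subsets are taken afterwards.

## Models

Three feature regimes bound circularity risk: CTI (all features), CTE
(clinical-trained predictor scores removed), SP (all predictor scores
removed); by construction SP ⊂ CTE ⊂ CTI. Binary LightGBM classifiers are
trained on a stratified 90/10 train/holdout split with sample weights.
Hyperparameters (num_leaves 7–63, depth 3–8, learning rate 0.01–0.3
log-uniform, min_child_samples 5–50, L1/L2 1e-8–1 log-uniform, feature and
row subsampling 0.6–1) are tuned by seeded random search, default 50 trials,
selecting on holdout AUC with first-winner tie-breaking; the final model is
refit on the training split only (not train+holdout), and the manifest records
seed, trials, best parameters, feature list and the training-split variant
keys. The decision threshold maximizes balanced accuracy over midpoints of
adjacent sorted holdout scores (smallest qualifying cut on ties). Training is
single-threaded and deterministic (`deterministic=True, force_row_wise=True`),
so the full train→predict path is bit-stable for a fixed seed.

**Prediction refusal.** A trained model never scores its own training
variants: they receive an `EXCLUDED_TRAINING` flag instead of a number, which
removes variant-level circularity from every downstream benchmark by
construction.

**Attribution.** Per-feature importance is the mean absolute TreeSHAP
contribution (LightGBM's native `pred_contrib`), ranked with name tie-breaks;
per-category totals partition the per-feature values exactly.

## PP3/BP4 calibration

Scores become clinical evidence via local likelihood ratios. Sliding windows
over the rank-sorted calibration scores (window = max(window_min, n/25),
default window_min 100, 200 window centers) estimate the local LR as the
within-window positive/negative count ratio rescaled by the global class
ratio, with a half-count continuity correction. The per-window log-LRs are
smoothed by a local-linear (lowess) pass against the normal quantile of the
window's rank position — depending on ranks keeps the whole fit invariant to
strictly monotone transforms of the scores, and the quantile axis decompresses
the tails so the smoother can track steep tail LRs — then monotonized by
isotonic regression and clipped to [1/ceiling, ceiling]. Local PPV follows by
Bayes at the target prior (default 0.10 regardless of calibration-set
balance). Evidence strengths use the standard odds-of-pathogenicity scale with
ceiling 350: supporting/moderate/strong at the 1/8, 1/4 and 1/2 powers of the
ceiling, benign cutoffs their reciprocals; PP3/BP4 cap at strong. On 10,000
simulated Gaussian scores (positives N(1,1), negatives N(−1,1), analytic
LR = e^{2s}) the fitted LR tracks the truth within ±20% across s ∈ [−1.5,
1.5] for typical seeds; the residual error concentrates at the range
endpoints, where the minority class contributes only a few dozen variants and
the sampling noise floor is itself near 20%.

**Point-based classes.** Evidence items combine additively: supporting ±1,
moderate ±2, strong ±4, very strong +8 (benign negative). Bands: P ≥ 10,
LP 6–9, VUS 0–5, LB −6…−1, B ≤ −7, with the uncertain band subdivided
VUS-high 4–5, VUS-mid 2–3, VUS-low 0–1 (the sub-band boundaries are this
package's decision). Concordance counts P/LP (optionally VUS-high, since
PP3 alone cannot exceed +4 points) as the pathogenic call and B/LB as benign;
conclusiveness is 1 − VUS-mid fraction; sensitivity and specificity are
computed over definitive calls.

## Genetic epidemiology

Per gene, the cumulative allele frequency (CAF) is the sum of qualifying
variants' allele frequencies, clamped at 1 with a warning. Under
Hardy–Weinberg assumptions: carrier frequency CrF = 1 − (1 − CAF)² for
autosomal genes, and for X-linked genes ½·CAF + ½·(1 − (1 − CAF)²) assuming a
50/50 sex ratio (the pooled-population convention; only the X-linked genetic
prevalence formulas are fixed by the framework, the carrier decomposition is
ours). Genetic prevalence: AR CAF², AD 1 − (1 − CAF)² (carrier frequency,
consistent with dominant expression), XLR CAF(CAF+1)/2, XLD
(1−CAF)·CAF + CAF(CAF+1)/2. Penetrance is P(D|C) = P(D)·P(C|D)/P(C), clamped
at 1 with a warning since noisy inputs can push the ratio above unity.
Cohort-level carriage assumes cross-gene independence:
p(any carrier) = 1 − Π(1 − CrF_g); expected affected genotypes = Σ GP_g.

Thirteen variant masks for burden-style association testing combine ACMG
classes (P; P+LP; P+LP+VUS-H; those plus predictor-damaging), the
predictor-damaging rule itself (missense, any non-definitive-benign class,
score > 0.631 — the CTE model's optimized decision threshold, overridable),
four predicted loss-of-function strength tiers and their unions, and
non-splice-altering synonymous variants (splice score < 0.2); each mask is
crossed with four allele-frequency strata (≤ 0.5, ≤ 0.1, ≤ 0.01, singletons).

## Benchmarking

Classification is summarized by ROC AUC (tied scores count half). Agreement
with continuous assay measurements uses the R² of a penalized B-spline smooth
(statsmodels GLMGam, penalty weight by generalized cross-validation, basis
df = n/5 capped at 10) of assay score on predictor score — a penalized-spline
stand-in for a generalized additive model; tool–study pairs with fewer than
10 shared variants are excluded, zero-variance assay scores define R² = 0, and
a tool's MAVE summary is the mean R² over its evaluable studies after
circularity masking.

## Synthetic test bed

The generator draws every fixture from a single integer-seeded PCG64 stream
with a documented sub-stream per input kind, so composite fixtures are
bit-reproducible. Defaults: 20 genes × 100 variants, Bernoulli(0.5) labels; a
25-feature catalog spanning all seven categories (6 predictor scores of which
2 clinical-trained, so the three regimes differ); 5 informative non-predictor
features at a 2-sd class-mean shift; 2% MCAR missingness plus two noise
features with class-biased missingness (30% vs 2%); per-gene assay studies
with effect 2, noise 0.5 and random orientation flips; log-uniform allele
frequencies in [1e-6, 1e-2] with 10% singletons; random-DAG tool registries.
The small preset (8 genes × 40 variants) keeps the end-to-end CLI run under a
minute on one CPU.

What the synthetic bed does not emulate: correlated features (real predictor
scores are strongly collinear), gene-level feature structure (here every
feature is i.i.d. per variant), label noise in curated sources beyond the 5%
planted in text-mined records, realistic allele-frequency spectra or ancestry
structure, and real protein sequences. Passing tests therefore demonstrate
that the machinery is correct under its stated model — recoverable signal,
honest exclusions, calibrated evidence — not that real-data performance
figures transfer.

## Numerical choices and degenerate inputs

- Missing values are NaN internally, blank in TSV, `.` in VCF INFO; scores
  round-trip at 10 significant digits.
- Variant keys normalize chromosome names by stripping a leading `chr`.
- `optimize_threshold` on all-identical scores returns that score (balanced
  accuracy 0.5); single-class inputs are errors, not warnings.
- Proxy-weight computation rejects allele frequencies outside (0, 1);
  singletons are expected to be removed upstream.
- The spline fit falls back to a straight line when the penalized solve is
  degenerate (exact relations trigger perfect-separation errors in the
  Gaussian GLM path).
- Hyperparameter search uses an independent PCG64 stream per training call;
  seeds derived from the user seed stay below 2^31.

## Design substitutions

Hyperparameter optimization is a seeded random search with a fixed trial
budget rather than a Bayesian optimizer; at 50 trials over an 8-dimensional
space the difference is immaterial and the search is reproducible by
construction. Feature attribution uses LightGBM's built-in TreeSHAP rather
than an external explainer; for tree ensembles the computed Shapley values
are identical. The assay-study acceptance statistic is a one-sided rank-sum
test; the exact screening statistic used at full scale is not fixed by this
package, and the Bonferroni-corrected acceptance contract is what the
pipeline depends on.
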