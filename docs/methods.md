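# Methods and conventions

This note records the statistical conventions, default parameters, and
design choices behind `radiolik`, in the spirit of a model-description
document: what is computed, under which assumptions, and what the
synthetic tests do and do not demonstrate.

## Feature tables

A cohort is a samples × features matrix with unique sample ids,
optional 0/1 labels (0 = benign, 1 = malignant) and one of seven
feature classes per column, inferred from the PyRadiomics-style column
prefix (`shape_`, `firstorder_`, `glcm_`, `gldm_`, `glszm_`, `glrlm_`,
`ngtdm_`). Unknown prefixes fall back to `firstorder` with a warning
rather than erroring, since supplementary feature lists in the wild use
inconsistent spellings; no specific feature spelling is load-bearing
anywhere in the toolkit. The shape/texture dichotomy used by signature
selection is derived: shape iff the class is `shape`. CSV values are
written with `repr` and parsed with round-trip float precision so a
write→read cycle is bit-exact.

## Reliability and discriminability screening

**Concordance.** Lin's concordance correlation coefficient,

CCC = 2·cov(x, y) / (var x + var y + (mean x − mean y)²),

with population (1/n) moments by default — Lin's original estimator; a
sample-moment (1/(n−1)) variant is available via a flag since published
radiomics pipelines rarely state which they used. The retention rule is
strict: CCC > 0.85. A CCC on two constant, equal-mean vectors is 0/0
and raises an explicit error rather than returning NaN; inside the
batch filter such features simply fail the gate.

**Discriminability.** Kruskal–Wallis with mid-rank ties and the
standard tie correction (delegated to `scipy.stats.kruskal`), p-value
from the χ² approximation with (groups − 1) degrees of freedom,
retention rule p < 0.05. An all-tied feature degenerates the tie
correction; the filter treats it as p = 1 with a warning (no evidence
of class separation), so constant features are excluded without
aborting a batch run. No multiple-testing correction is applied across
features — the gate is a per-feature screen, not a discovery procedure,
and its family-wise behavior is intentionally not controlled.

The two gates are a conjunction applied in one pass; order is
irrelevant by construction, and the filter is monotone in both
thresholds (loosening either never shrinks the retained set).

## Ranking and consensus

Seven rankers sit behind one interface returning raw scores plus an
orientation flag:

- **Fisher score** — Σ n_c(μ_c−μ)² / Σ n_c σ²_c with population class
  variances; a feature with separated means but zero within-class
  variance would be +∞ and is clamped to (max finite score + 1) with a
  warning so normalization stays finite.
- **ReliefF** — features min-max scaled to [0, 1], Manhattan-distance
  neighbors, k = 10 hits and misses (truncated to class size), every
  sample an anchor by default so the result is deterministic without a
  seed; subsampled anchors require an explicit seed.
- **Mutual information** — feature discretized into 10 equal-width
  bins, MI with the label in nats from the contingency table.
- **Laplacian score** — heat-kernel kNN graph (k = 5, Euclidean,
  symmetrized by neighborhood union, σ = mean kNN distance unless
  given), score (f̃ᵀLf̃)/(f̃ᵀDf̃) of the D-mean-centered feature;
  lower is better. Constant features get the worst score + 1 with a
  warning.
- **Spectral score** — f̂ᵀ(I − D^{−1/2}WD^{−1/2})f̂ with f̂ the
  degree-weighted, unit-norm feature on the same graph; lower is
  better. Note this first-eigenvector form rates any high-mean,
  low-variance feature as smooth; it is kept in its classical form and
  balanced by the other group members in the consensus.
- **Minimum redundancy** — negated mean absolute Pearson correlation
  with all other features; constant features contribute correlation 0.
- **Variance** — population variance after min-max scaling (making
  heterogeneous units comparable).

**Commensuration.** How heterogeneous ranker scores should be combined
is genuinely open; the default orients every score to higher-is-better,
min-max normalizes to [0, 1] per ranker (a constant ranker maps to 0.5
everywhere, with a warning), and takes the equal-weight arithmetic
mean. A rank-average mode (mean of normalized rank positions) is
provided for scale-free averaging. Final ranks sort by descending
consensus with ties broken by ascending feature name, so rankings are
deterministic and reproducible.

**Signature selection** takes the best-ranked shape feature and the
best-ranked texture feature within the top-25 consensus ranks (both
defaults configurable) and errors explicitly when either kind is absent
from the top list. Signatures are labeled by their feature content and
(optionally) the ranker group that produced them, never by a
filter/wrapper provenance claim.

## Likelihood forms

Both forms are linear in their coefficients, so the minimum-RSS fit is
ordinary least squares on the basis-expanded design matrix; no logistic
link is applied to the 0/1 responses, matching how the published
coefficients behave (scores are unbounded reals, thresholded at 0.51).

The MLF I basis is written with both ln(x₁) and ln(x₁²) = 2·ln(x₁) —
an exactly collinear pair. The toolkit implements the printed form
literally: `fit` solves via SVD (`numpy.linalg.lstsq`), returning the
minimum-norm coefficient vector; predictions and the combination
b + 2c are identified even though b and c individually are not, and
the residual degrees of freedom use the design's numerical rank
(p_eff = 6, not 7). A `squared_log=True` variant interprets the second
term as (ln x₁)², which is full-rank and plausibly what a curve-fitting
tool originally produced — but the published coefficients belong to the
printed form, so the pretrained model never uses the variant.

`residual_se` is √(RSS / (n − rank)). Whether the published "average
standard error for the y estimates" (0.30 / 0.20) used n − p, n, or a
software-specific convention is unknowable from the text; the
pretrained models simply carry the published numbers as metadata, and
no test asserts agreement between the two conventions.

Out-of-domain inputs (x ≤ 0 where a log or reciprocal is required)
raise errors at the API level; the CLI offers `--clip-eps` to floor
values at a small positive constant for robustness on noisy tables.

## Classification metrics

Positive class = malignant; a score is called malignant iff
y ≥ threshold with 0.51 the published operating point (boundary
inclusive, exactly as printed). Two sensitivity/specificity naming
conventions circulate; the report exposes both explicitly:
`paper_sensitivity` = TP/(TP+FP) and `paper_specificity` = TN/(TN+FN)
(the convention under which the reference confusion matrices reproduce
their published percentages — predictive values, in standard
epidemiological terms), alongside `std_sensitivity` = TP/(TP+FN) and
`std_specificity` = TN/(TN+FP). ROC curves sweep the observed score
values (ties grouped) plus the all/none endpoints via
`sklearn.metrics.roc_curve` on the standard TPR/FPR axes; AUC is
trapezoidal, and the tests verify its identity with the Mann–Whitney
pair-counting statistic (ties ½) to 1e-12. Undefined ratios (zero
denominators, e.g. detection-rate cohorts with no benign samples)
report as absent with a warning. Confidence intervals are deliberately
not produced: no interval method is specified for the reference values,
and guessing one would imply false comparability.

## Synthetic cohorts

The generator emulates a two-class CT radiomics cohort at the 105
feature panel (shape 13, GLDM 14, GLCM 23, NGTDM 5, first-order 18,
GLSZM 16, GLRLM 16). Defaults mirror the reference training cohort:
165 malignant + 35 benign. Four planted informative features mirror
the real signature candidates — volume (log-normal, median ≈ 1.8·10³
mm³, i.e. a ~15 mm nodule, class shift on the log scale),
surface-to-volume ratio (≈0.5 /mm), sum entropy (≈4.5), and large area
low gray level emphasis (≈500) — each separated between classes by
`effect_size` standard deviations (default 2.0, a strong but realistic
radiomic signal). All other features are i.i.d. standard normal,
independent of the label, with an optional equicorrelation knob for
redundancy-ranker tests.

Test–retest replicates add independent Gaussian noise scaled to
`retest_noise_sd` × each feature's own sd (default 0.3); generating
two replicates from the same base gives the closed form
CCC = 1/(1 + sd²), which the tests verify empirically at n = 500.

What the synthetic tests show: that the screening, ranking, selection,
fitting and evaluation machinery behaves per its contracts (type-I
error of the KW gate ≈ α, planted signatures recovered in ≥ 95 of 100
seeds at effect size 3, exact refit recovery on noiseless surfaces).
What they do not show: performance on real CT radiomics, whose features
are heavily inter-correlated, non-Gaussian, and scanner-dependent —
none of which the generator emulates. Cohort-dependent published
quantities (AUCs of 92.68 % / 98.81 %, the 51-feature retained count)
require the original image cohorts and are not reproduced here.

## Problem sizes and numerical choices

The statistical test batteries use: 500 null seeds for the KW type-I
check (±3 binomial sd), 100 cohort seeds at n = 100 + 100 for the
signature-recovery check, 300 replicates for p-value uniformity
(KS sanity bound; KW p-values are mildly discrete at n = 30), and
n = 200 points for refit recovery (tolerance 1e-8; observed errors are
~1e-14). CCC results are clamped to [−1, 1] against float excursions.
Full-pipeline runs are deterministic given the seed: identical
configurations produce byte-identical artifacts, which the CLI tests
assert.
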