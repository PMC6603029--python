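# radiolik

A toolkit for building and applying **radiomics-driven likelihood models**
for CT tumor classification. It operates entirely on tabular radiomic
feature data (one row per tumor/nodule, PyRadiomics-style `class_Name`
columns) and covers the full diagnostic-signature workflow:

1. **Reliability / discriminability screening** — features must pass a
   test–retest concordance gate (Lin's CCC > 0.85 between paired repeat
   scans) *and* a Kruskal–Wallis discriminability gate (p < 0.05 against
   the benign/malignant label).
2. **Consensus feature ranking** — a bank of supervised (Fisher score,
   ReliefF, mutual information) and unsupervised (Laplacian score,
   spectral score, minimum-redundancy, variance) ranking algorithms;
   each ranker's scores are oriented to higher-is-better, min-max
   normalized, and averaged with equal weights.
3. **Signature selection** — one shape feature plus one texture feature,
   each the highest-ranked of its kind within the top-25 consensus list.
4. **Likelihood models** — two published functional forms mapping a
   signature pair (x₁, x₂) to a malignancy score y (≈0 benign, ≈1
   malignant):

   **MLF I** (x₁ = volume, x₂ = large area low gray level emphasis):

       y = a + b·ln(x₁) + c·ln(x₁²) + d/x₂ + e/x₂² + f/x₂³ + g/x₂⁴

   **MLF II** (x₁ = surface-to-volume ratio, x₂ = sum entropy):

       y = a + b·x₁ + c·x₁² + d·x₁³ + e·x₁⁴ + f·ln(x₂)

   Both are available pretrained (published coefficients at full
   precision) and refittable by ordinary least squares on new cohorts —
   the forms are linear in their coefficients.
5. **Classification and evaluation** — threshold y ≥ 0.51 ⇒ malignant;
   confusion matrices, accuracy, both sensitivity/specificity naming
   conventions, ROC curves and trapezoidal AUC.

A seeded synthetic-cohort generator (105 features in the standard
shape/GLCM/GLDM/GLSZM/GLRLM/NGTDM/first-order panel, four planted
informative features, controllable effect size and retest noise) makes
every stage testable without any image data.

## Worked example

Simulate a 200-nodule cohort with a test–retest replicate pair, then run
the full pipeline:

```sh
radiolik simulate --n-malignant 100 --n-benign 100 --effect-size 2.5 \
    --seed 17 --out cohort.csv --retest-out a.csv,b.csv --retest-noise 0.2
radiolik run --table cohort.csv --out-dir out --seed 17
```

which prints the artifact produced by each stage:

```
wrote 200 x 105 cohort to cohort.csv
filter: out/filter_report.csv
rank: out/ranking.csv
signature: out/signature.json
fit: out/model.json
predict: out/scores.csv
evaluate: out/evaluation.json
```

With this seed the screening retains 9 of 105 features (the four
informative ones plus a handful of chance Kruskal–Wallis passes among
101 noise features — about what α = 0.05 predicts), the supervised
consensus signature is
`shape_SurfaceVolumeRatio` + `glszm_LargeAreaLowGrayLevelEmphasis`, and
`out/evaluation.json` reports

```
confusion: tp 97, fn 3, fp 2, tn 98
accuracy 0.975   sensitivity 0.980   specificity 0.970   AUC 0.997
```

i.e. the fitted MLF II surface with the 0.51 threshold separates the
two classes almost perfectly at this planted effect size.

Scoring a single nodule with the published MLF II model from Python:

```python
from radiolik import FeaturePair, classify, evaluate, pretrained

model = pretrained("MLF2")
y = evaluate(model, FeaturePair(x1=0.35, x2=4.1))  # SVR, sum entropy
print(y, classify(y))   # 1.0057793470231302 1  -> malignant
```

## Layout

- `src/radiolik/core_tables.py` — feature-table data model, CSV I/O,
  feature-class inference
- `src/radiolik/qa_filter.py` — CCC, Kruskal–Wallis, retention filter
- `src/radiolik/ranking.py` — ranker bank, consensus averaging,
  signature selection
- `src/radiolik/likelihood.py` — MLF I / MLF II bases, pretrained
  coefficients, least-squares fitting
- `src/radiolik/evaluation.py` — classification, confusion matrices,
  metrics, ROC/AUC
- `src/radiolik/synthetic.py` — seeded cohort / retest / model-surface
  generators
- `src/radiolik/cli.py` — `radiolik` command-line interface

See `docs/methods.md` for the statistical conventions, parameter
defaults, and known limitations.
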