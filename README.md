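# ppidvm

Sequence-based prediction of protein–protein interactions (PPIs) from
evolutionary profiles. Given a PSI-BLAST position-specific scoring
matrix (PSSM) for each protein — an L×20 matrix of integer log-odds
substitution scores encoding per-residue conservation — the package:

1. summarises each PSSM with an **improved Weber Local Descriptor
   (IWLD)**: at every matrix cell it computes a differential-excitation
   component ξ = arctan(Σⱼ(xⱼ−xᵢ)/xᵢ) over the 8-neighbour ring
   (bounded in [−π/2, π/2]) and an orientation component
   γ = atan2(v₁₁, v₁₀) + π from the 3×3 Sobel derivative pair, then
   quantises (ξ, γ) into an M×T joint histogram per V×H sub-block.
   At the defaults M = T = 8, V = H = 2 each protein becomes a
   256-dimensional histogram;
2. concatenates the two descriptors of a pair into a 512-dimensional
   vector and reduces it to 200 principal components;
3. classifies with the **Discriminative Vector Machine (DVM)**: for
   each query y it finds the k nearest training vectors X_k and solves

   min_β (y − X_k β)ᵀ P (y − X_k β) + δ‖β‖² + γ βᵀ L β

   by half-quadratic alternation, where P carries Welsch M-estimator
   weights pᵢ = exp(−rᵢ²/σ²) (σ² = θ·rᵀr/d) that damp outlying
   residual coordinates, and L = D − W is the graph Laplacian of the
   neighbours' cosine-similarity graph. The query is assigned the class
   whose neighbours reconstruct it with the smallest residual
   ‖y − X_{k,i} β_{k,i}‖. Defaults: δ = 1e−3, γ = 1e−4, θ = 1,
   k = min(n_train, 40).

Evaluation is stratified 5-fold cross-validation reporting accuracy,
sensitivity, precision, Matthews correlation and ROC AUC, with an
RBF-kernel SVM baseline (C = 0.6, γ = 0.01) run on identical folds.

A synthetic-data module generates PSSM-shaped matrices with a
controllable class-separating texture signal, so the complete pipeline
runs and is tested without any database search; the intended production
inputs are PSI-BLAST `-out_ascii_pssm` files plus a tab-separated
`id_a  id_b  label` pair list. The package is for computational
biologists screening candidate interaction pairs from sequence alone.

## Worked example

```sh
$ ppidvm synth --n-pairs 120 --effect 3.0 --seed 4 --out-dir demo
wrote 240 PSSMs and 120 pairs to demo

$ ppidvm cv --pssm-dir demo --pairs demo/pairs.tsv \
            --out demo/report.json --seed 4 --n-components 40
acc: 0.9917 +/- 0.0186
sen: 1.0000 +/- 0.0000
pre: 0.9846 +/- 0.0344
mcc: 0.9840 +/- 0.0358
auc: 1.0000 +/- 0.0000
```

`synth` writes 240 synthetic PSSM files and a labelled pair list in
which interacting pairs share a texture regime and non-interacting
pairs mix two regimes (`--effect` controls the contrast; 0 is a null
dataset). `cv` runs the full IWLD → PCA → DVM pipeline under stratified
5-fold cross-validation: on this strongly separable dataset the
classifier recovers the planted signal almost perfectly (mean accuracy
99.2%, every fold's AUC 1.0; ± values are fold-wise sample standard
deviations). Beside the JSON report it writes per-fold metrics
(`report.folds.csv`) and ROC points (`report.roc.csv`). `--classifier
svm` (or the `baseline-svm` subcommand) evaluates the SVM reference on
the identical folds; `train`/`predict` fit and apply a persistent model
archive.

The same pipeline is available as a library:

```python
from ppidvm import synth_pair_dataset, cross_validate
pssms, pairs = synth_pair_dataset(400, (30, 80), effect=3.0, seed=11)
report = cross_validate(pairs, pssms, seed=11)
print(report.mean["acc"])   # 0.995
```

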