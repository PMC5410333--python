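# Methods

## Problem and model

The package predicts whether two proteins interact using only
evolutionary profile information. Each protein is represented by its
PSI-BLAST position-specific scoring matrix (PSSM): L rows (residue
positions) × 20 columns (amino acids) of integer log-odds substitution
scores. The premise is that interaction leaves a signature in the local
*texture* of conservation patterns, so the PSSM is treated as a
grayscale image and summarised with a local texture descriptor; pairs
are then classified by a robust per-query reconstruction classifier.

How the PSSMs were produced (database, iteration count, E-value) is the
caller's choice: the parser accepts any standard `-out_ascii_pssm`
file, consuming only the 20-column log-odds block and ignoring the
percentage block and footer statistics.

## The IWLD descriptor

At each cell xᵢ of the (scaled) matrix:

* **Differential excitation** ξ = arctan(Σⱼ(xⱼ − xᵢ)/xᵢ), summing over
  all p = 8 neighbours of the 3×3 ring. The arctan compresses the
  Weber-style relative change into [−π/2, π/2]. The denominator is
  max(xᵢ, ε) with ε = 1e−8.
* **Orientation** γ = atan2(v₁₁, v₁₀) + π ∈ [0, 2π), where v₁₀ and v₁₁
  are the horizontal and vertical responses of the standard 3×3 Sobel
  pair ([[−1,0,1],[−2,0,2],[−1,0,1]] and its transpose). Using the full
  8-neighbour Sobel stencil rather than 4-neighbour differences keeps
  more orientation information and suppresses noise.

ξ is quantised into M uniform bins over [−π/2, π/2] (bin m covers
[(m/M − ½)π, ((m+1)/M − ½)π), top edge closed); γ into the nearest of
T dominant directions Φₜ = 2πt/T with wraparound,
t = ⌊γ/(2π/T) + ½⌋ mod T. The matrix is split into V row-bands × H
column-bands (band sizes ⌊L/V⌋ with the remainder in the last band,
blocks ordered row-band-major) and each block's M×T joint histogram,
flattened m-major, is concatenated. Defaults M = T = 8, V = H = 2 give
256 values per protein; a pair is the 512-long concatenation
(id_a first). PCA (mean-centred, fitted on training data only) reduces
pairs to 200 components.

### Numerical choices

* **Intensity scaling.** Raw scores can be zero or negative, but the
  excitation denominator must be positive. Scores are mapped through
  the logistic 1/(1+e⁻ˢ) into (0, 1) — order-preserving and bounded —
  before filtering. `scale=False` runs raw scores with only the ε
  guard.
* **Borders** are replicate-padded so every cell, including the edges
  of the 20-wide matrix, has 8 neighbours; hence the conservation law
  that raw counts sum to exactly L·20.
* **Flat regions.** Both Sobel responses vanish on constant
  neighbourhoods; atan2(0,0) is fixed to 0, so flat texture lands
  deterministically at γ = π (bin t = T/2). Responses below
  1e−10·max(1, |m|∞) are snapped to exact zero first, because floating
  point accumulation otherwise gives flat regions an arbitrary
  noise-chosen direction.
* Histograms default to raw counts (keeps the mass-conservation
  invariant testable); per-block L1 normalisation is available
  (`normalize=True`).
* Minimum protein length is L = 2; curation filters such as dropping
  sequences ≤ 50 residues are dataset policy, exposed as the CLI's
  `--min-length` option rather than enforced by the types.

## The DVM classifier

For query y with k nearest training samples (Euclidean metric on the
PCA features; k defaults to min(n_train, 40), enough to cover both
classes with high probability at typical dataset sizes):

minimise over β:  (y − X_k β)ᵀ P (y − X_k β) + δ‖β‖² + γ_reg βᵀ L β

with samples as *columns* of X_k, so the residual r = y − X_k β is
indexed by feature i = 1..d and P = diag(pᵢ) is d×d. The Welsch
M-estimator φ(x) = ½(1 − e^(−x²)) induces the weights
pᵢ = exp(−rᵢ²/σ²) with kernel size σ² = θ·rᵀr/d (all pᵢ = 1 when
r = 0). W is the cosine similarity of the neighbour rows clipped to
[0, 1] — a Laplacian smoothness penalty needs nonnegative similarities,
so "cosine distance" is realised as similarity — with diagonal 1 and
zero-norm rows given similarity 0; L = D − W, and
βᵀLβ = Σ_{p<q} w_pq(β_p − β_q)² pulls coefficients of similar
neighbours together.

For fixed P the minimiser is closed-form,
β = (X_kᵀ P X_k + δI + γ_reg L)⁻¹ X_kᵀ P y, and δ > 0 guarantees
invertibility. Since P itself depends on β, the solver alternates
(half-quadratic minimisation): initialise P = I, repeat
[solve; update (P, σ)] until ‖Δβ‖∞ < 1e−6 or 50 iterations
(`single_step=True` keeps the literal one-shot P = I solve). Each
solve is the exact minimiser of its fixed-P objective, so that
objective never increases within an iteration.

Class residuals Rᵢ = ‖y − X_{k,i} β_{k,i}‖₂ use only the neighbour
columns of class i; a class absent from the neighbourhood receives the
empty-dictionary fit Rᵢ = ‖y‖₂. Prediction is argmin Rᵢ with ties
broken toward the smaller class id. Classes: 1 = non-interacting,
2 = interacting. The ROC score is the scale-free residual margin
(R₁ − R₂)/(R₁ + R₂), positive when the interacting class fits better.

Defaults δ = 1e−3, γ_reg = 1e−4, θ = 1; performance is insensitive to
these within an order of magnitude.

## Evaluation protocol

Stratified 5-fold cross-validation with a fixed seed: one partition,
all five folds evaluated ("repeats" redraws the partition with derived
seeds and pools folds). Per fold, PCA is fitted on the training rows
only (the leakage-free default; `pca_global=True` reproduces the
whole-dataset fit some studies use), the requested component count
capped at min(n_train − 1, d) with a log note when the fold is small.
Metrics: Acc = (TP+TN)/N, Sen = TP/(TP+FN), Pre = TP/(TP+FP),
MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)), plus trapezoidal
AUC. Degenerate denominators (no positives predicted, zero MCC factor)
yield 0 with a warning instead of an error. Summary rows are mean ±
fold-wise *sample* (n−1) standard deviation. The SVM baseline
(RBF kernel, C = 0.6, γ = 0.01) runs on byte-identical folds and emits
the same report schema. Cross-dataset evaluation fits PCA and the DVM
on the full training dataset and scores a held-out dataset.

## Synthetic data: what it emulates and what it does not

`synth_pssm` produces integer matrices clipped to the typical
PSI-BLAST score range [−16, 13] in three texture regimes — `smooth`
(Gaussian field low-passed with σ = 2, low local gradients), `rough`
(i.i.d. rounded Gaussian noise) and `motif` (period-4 ±amplitude row
stripes with a random phase) — chosen to be distinguishable precisely
through the gradient statistics the descriptor measures.

`synth_pair_dataset` builds each protein as
round(3·N(0,1) + effect·signal), where the unit-variance signal is the
smooth field (regime A) or the stripe pattern (regime B). Interacting
pairs join two regime-A proteins; non-interacting pairs join one A and
one B in random order, so the class signal lives entirely in the
texture contrast and scales with `effect`: at effect = 0 the regimes
coincide and labels are independent of features; at effect = 3 (the
documented study condition, 400 pairs, lengths 30–80) the planted
signal is strong enough that the pipeline should recover it almost
perfectly. Datasets are balanced by construction and bit-reproducible
per seed.

Passing on this generator shows the machinery is correct — the
descriptor separates texture regimes, PCA and the classifier recover a
planted pairwise signal, the nulls sit at chance — but *not* that real
PPIs are predictable at any particular accuracy: real PSSMs have
residue-composition structure, length/conservation correlations, and
negative pairs chosen by subcellular localisation, none of which the
generator emulates. Published-scale accuracies on curated yeast/human
datasets require the original data plus PSI-BLAST runs and are out of
scope here.

The test suite and acceptance script use 120–400 pair datasets and
20-instance solver checks; these sizes make the full suite run in well
under a minute on one CPU while leaving the statistical assertions
(binomial CI at n = 400, ≥95% recovery) well powered.

## Known limitations

* Neighbour search is a brute-force distance scan per query; fine at
  thousands of training pairs, no indexing structures for larger sets.
* The SVM baseline's fixed (C, γ) were tuned for other feature scales;
  on raw-count synthetic features it ranks well (AUC ≈ 1) but
  thresholds poorly. It is a protocol baseline, not a tuned competitor.
* Binary classification only; no probability calibration, no
  kernelised DVM, no multi-scale or overlapping descriptor blocks.
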