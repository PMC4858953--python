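# Methods

## Model

`msishrink` implements nearest-shrunken-centroids analysis of MS imaging
data with spatially aware distances. The data are N pixel spectra x_n over
P features, each pixel carrying integer grid coordinates (i, j) and a
sample identifier; samples need not be rectangular and are stored as
explicit coordinate lists.

**Shrunken centroids.** For classes/segments k = 1..K with sizes N_k:

- class centroids x̄_k (per-class means), overall centroid x̄ (mean over
  all pixels, not the mean of class means);
- pooled within-class SD per feature
  τ̂_p = √( Σ_k Σ_{n∈k} (x_np − x̄_kp)² / (N − K) );
- standardized statistic t_kp = (x̄_kp − x̄_p) / (m_k (τ̂_p + s₀)) with
  m_k = √(1/N_k − 1/N), the standard error factor of the numerator;
- soft threshold t′_kp = sign(t_kp)(|t_kp| − s)₊;
- shrunken centroid x̄′_kp = x̄_p + m_k (τ̂_p + s₀) t′_kp, the exact
  inverse of the standardization, so s = 0 reproduces the class means and
  t′_kp = 0 pins a feature exactly to the overall mean.

s₀ is an optional offset stabilizing zero-variance features (default 0;
when a fit encounters τ̂_p = 0 it falls back to the conventional
median-τ̂ offset for that fit and records it on the model).

**Spatial distances.** Neighborhoods are square Chebyshev windows of
radius r restricted to same-sample pixels; windows truncate at edges and
irregular footprints (no padding), and weights are renormalized to sum
to 1 per pixel. SA weights are Gaussian in the squared offset with
bandwidth σ (default r/2, placing the window edge near two bandwidths).
SASA weights multiply in β = exp(−‖x_neighbor − x_center‖²/(2λ²)) with λ
set per neighborhood to half the norm of the difference between its two
most differing spectra; λ = 0 (identical spectra) falls back to pure
Gaussian weights. Since the weights depend only on the observed spectra,
they are computed once per image and reused across all fits and
iterations. The distance from pixel n to centroid c is the weighted
average over the window of the plain squared distances
Σ_p ((x_p − c_p)/(τ̂_p + s₀))² — a convex combination, so the spatial
distance always lies between the minimum and maximum of the neighbors'
plain distances.

**Probabilities.** By the regularized-LDA analogy (shared diagonal
covariance), score_k = d²_k − 2 log π_k and
p_k = exp(−score_k/2) / Σ_l exp(−score_l/2), computed with
max-subtraction. Because spatial averaging mixes neighboring spectra into
each distance, these are membership probabilities in the empirical sense,
not calibrated Gaussian posteriors. Hard assignment is the argmax with
ties resolved to the lowest class index, deterministically.

## Unsupervised segmentation

From K initial segments (default initialization: k-means on the spectra,
for cross-platform reproducibility; uniform random labels and SA
clustering are also available), each iteration:

1. drops empty segments and renumbers the rest preserving order;
2. fits the shrunken-centroid summary at shrinkage s;
3. **removes spurious segments**: a segment whose entire t′ row is zero
   has no informative feature — its shrunken centroid coincides with the
   overall centroid, so no feature matters when assigning pixels to it.
   Such segments otherwise survive indefinitely as "catch-alls" for
   boundary and middle-ground pixels whose smoothed spectra sit near the
   overall mean, stalling the segment count one above the truth. If
   *every* segment is noninformative (the full-shrinkage limit) they are
   all kept and deterministic tie-breaking collapses the segmentation to
   a single segment instead;
4. computes spatial distances to the shrunken centroids and reassigns
   every pixel by maximum probability, with uniform priors 1/K over the
   current segments (empirical priors are available but off by default).

Iteration stops when no pixel changes label, when fewer than 0.1 % of
pixels change, or at `max_iter` (default 20); all three are logged. The
reported model and probabilities are refit from the final labels, so the
output invariants hold exactly: labels are the argmax of the reported
probabilities and every reported segment is nonempty. τ̂ is recomputed
from the current labels at every iteration, and shrinkage applies from
the first iteration.

**Parameter selection.** `param_grid` fits one segmentation per (K, s)
cell; `select_params` returns the smallest s at which the final segment
count agrees across all initial K and is unchanged at the next larger s.
If no s qualifies it returns the largest s with agreement across K and
flags the selection as not stabilized — segmenting data with no clear
structure is reported as such rather than silently resolved.

## Supervised classification

`fit_classifier` is a single pass (no iteration) with empirical priors
N_k/N by default. `predict` builds neighborhoods and weights on the
prediction image's own geometry and requires an exact feature match to
the training m/z axis (a tolerance matcher is available via `mz_tol`).
`cross_validate` is leave-one-sample-out: each sample is an experimental
unit; no pixel of a held-out sample influences its fold's centroids, τ̂
or t′. The chosen s maximizes pooled held-out accuracy; ties resolve
toward larger s (stronger shrinkage and fewer features at equal
accuracy). Folds whose training part lacks a class are skipped with a
warning and excluded from the mean.

## Phantom generator

`make_phantom` emulates a controlled ground-truth imaging experiment: a
label image of K_true spatial regions (default 40×40 with background, a
disk and a stripe), baseline intensity 1 everywhere, plus
`effect_size`·`noise_sd` on each segment's own `enriched_per_segment`
features inside that segment (disjoint blocks of features per segment),
i.i.d. Gaussian noise of SD `noise_sd`, clipped at zero. Everything is a
deterministic function of the seed (PCG64). Defaults: P = 50, 5 enriched
features per segment, effect 3, noise 1 — strong, sparse signal at a size
where a full parameter grid fits in seconds.

With `correlated_noise_radius` > 0 the noise field is smoothed with a
Gaussian filter of bandwidth radius/2 per sample (the same bandwidth
convention as the spatial weights) and rescaled to the stated marginal
SD, mimicking spatially correlated acquisition noise. A log-normal noise
option exists for heavier-tailed realism.

What the phantom does *not* emulate: realistic peak shapes, isotope
envelopes, matrix effects, intensity-dependent (Poisson-like) noise, or
correlated features. Passing the phantom studies therefore demonstrates
the statistical mechanics of the method — feature selection, segment
elimination, uncertainty localization — not instrument-level robustness.

`segmentation_accuracy` scores a predicted labeling by the best
one-to-one matching of predicted to true labels (Hungarian assignment on
the contingency table); pixels of unmatched predicted labels count as
errors, so inventing extra segments is penalized.

## Study designs and problem sizes

- Segment-count/feature/uncertainty recovery: default phantoms, parameter
  grid K ∈ {6, 10} × s ∈ {0..6}, r = 1, SA weights, 20 replicates in the
  test suite and 10 in the acceptance script.
- Spatial benefit vs. k-means: at the default effect size (3 noise-SD on
  5 features each) single pixels are separable at ≈ √10·3 SD and k-means
  is already at the accuracy ceiling, so no spatial method can exceed it.
  The comparison is therefore run in the weak-signal regime
  (effect 1 noise-SD, per-pixel Bayes error ≈ 10 %) with correlated noise
  radius 1, K = 3 for both methods and s = 3 (grid midpoint), where
  neighborhood averaging has information to add.
- Cross-validation: four-sample two-class (half/half) 16×16 phantoms at
  effect 1, s grid {0..6}.

## Numerical and design choices

- Rendered forms of the t-statistic denominator and of the probability
  formula are ambiguous in places; the package pins
  m_k = √(1/N_k − 1/N) by the standard-error interpretation and the
  softmax exp(−score/2) by the Gaussian-likelihood analogy, both the
  standard choices in the nearest-shrunken-centroids literature.
- The Gaussian weight normalization constant cancels under per-pixel
  renormalization and is omitted.
- Feature ranking ties break by ascending m/z; argmax ties by lowest
  index; label renumbering preserves order — all outputs deterministic.
- In the pairwise SA/SASA distance between two pixels, offsets present in
  only one window are dropped and the weights renormalized over the
  shared offsets.
- The SA/SASA clustering baselines assign pixels by the pixel-to-centroid
  spatial distance with unit feature scale (the centroid acts as its own
  uniform neighborhood); centroid updates are plain segment means. With
  r = 0 they reduce exactly to k-means.
- k-means and PCA baselines use scikit-learn with a fixed `random_state`;
  everything else draws from `numpy.random.default_rng(seed)`.

## Limitations

- Neighborhoods are 2-D and isotropic; no 3-D (z-stack) or learned
  kernels.
- The probabilities are not frequency-calibrated; they are a ranking and
  visualization device (transparency maps), as used here.
- Shrinkage-driven segment elimination assumes the noise is approximately
  exchangeable across pixels; noise spatially correlated *above* the
  smoothing scale can sustain spurious segments with genuinely large t′
  (visible on correlated-noise phantoms), which is a property of the
  statistic, not an implementation artifact.
- Peak picking, baseline correction, smoothing and mass recalibration are
  upstream: the method expects detected, aligned, quantified features.
  Only TIC normalization and fixed-width m/z binning are provided as
  plumbing.
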