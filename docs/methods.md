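# Methods

This note documents the models and numerical choices behind `wavefbn`:
what each stage assumes, which parameters matter, what the synthetic
cohorts do and do not emulate, and where the design was genuinely open.

## Unit-rate resampling and the frequency convention

The pipeline analyses every cohort on a common "unit-rate" axis whose
nominal sampling interval is 1 s, regardless of the acquisition TR. The
convention is that *relabelling* the sampling interval from TR seconds to
1 s multiplies every physical frequency by TR: a 0.05 Hz component in a
TR = 3 s recording appears at 0.15 cycles/sample, and the resting-state
band 0.01–0.08 Hz maps to 0.03–0.24 — which is exactly the default
wavelet analysis range (`map_physical_band`).

`resample_to_unit_rate` implements this by relabelling the interval and
extending the series periodically from `m` to `round(m·TR)` samples, so
the per-sample frequency content is preserved while the series reaches
the length a 1 Hz recording of the same duration would have (80 points at
TR = 3 s become 240). A linear trend is removed before the extension —
a trend would otherwise create a seam discontinuity at each period
boundary — and the channel mean is restored afterwards. The alternative,
duration-preserving band-limited interpolation, would leave physical
frequencies unchanged on the unit-rate axis (0.01–0.08 Hz content at
0.01–0.08 cycles/sample) and hence leave the upper analysis bands with no
signal; the relabelling convention keeps the full analysis grid live and
is the convention the rest of the package is calibrated to. Periodic
extension does mean the extended samples repeat earlier ones: the
effective number of independent time points is that of the original
record, which matters for the variance (not the validity) of downstream
estimators.

## Morlet wavelet decomposition

`fcwt_decompose` computes, per ROI and band, the inverse FFT of the
signal spectrum multiplied by the conjugated spectrum of an analytic
Morlet wavelet dilated to the band's centre frequency. Parameters:

- `morlet_omega0` (default 6.0) — dimensionless centre frequency; 6 is
  the standard analytic Morlet, giving a relative frequency resolution of
  roughly f/6 per band. Values below 5 are rejected (the analytic
  approximation degrades).
- `f0`, `f1`, `fn` (defaults 0.03, 0.24, 10) — analysis range and band
  count; spacing is linear by default, with a geometric
  (`"logarithmic"`) option. With the defaults the inter-band step is
  0.7/30 ≈ 0.0233 cycles/sample.
- Boundary handling: the signal is reflect-padded to the next power of
  two before the FFT and the result truncated back, confining circular
  wrap-around to the wavelet support near the record edges.

At the lowest band (0.03) the wavelet spans ~32 samples, so a 240-sample
record holds only a handful of independent coefficient values there; all
dependence estimates are noisier, and spuriously larger, at low bands.
This is inherent to time–frequency analysis of short records, and it is
why the band-adaptive maximum below is paired with permutation gating.

## Dependence measures

**Complex correlation (CCC).** `r_c` is the Pearson-type correlation of
complex coefficient series using the conjugate of the second argument.
|r_c| ≤ 1 by Cauchy–Schwarz; real inputs reduce exactly to Pearson.
Significance is assessed by Monte Carlo permutation: one series' time
indices are permuted B times (default 1000) and
p = (1 + #{|r_c,b| ≥ |r_c|})/(1 + B), an exact-level test under
exchangeability. Full random permutation destroys autocorrelation, which
makes the test anti-conservative for smooth band-limited signals; a
circular-shift surrogate that preserves autocorrelation is available
(`scheme="circular"`). Within a subject the same surrogate set is shared
across edges, which preserves per-edge validity and saves regenerating
B permutations per pair.

**Mutual information.** Estimated from the Gaussian-KDE joint density of
the two scalar signal views on a `grid_points²` lattice spanning the data
range ± 3 bandwidths, integrated by trapezoidal quadrature; negative
quadrature results clip to 0, and the estimator is made exactly symmetric
by canonicalising argument order. Choices that matter:

- *Signal view*: complex coefficients enter as magnitudes (band
  envelopes) by default — envelope co-modulation is the standard carrier
  of band-limited nonlinear dependence and is phase-invariant; a
  `real_part` view is available.
- *Bandwidth*: Silverman's rule h = 1.06·σ̂·n^(−1/5) per marginal
  (default), or a fixed h.
- *Kernel covariance*: the joint kernel's covariance is scaled to the
  sample covariance (`kernel_cov="matched"`, default). A product kernel
  with independent axes smooths the joint more than the marginals in the
  correlated direction, shrinking the apparent correlation by 1/(1+h²)
  — at n = 2000 and ρ = 0.8 that alone biases MI ≈ −15%. The matched
  kernel leaves the smoothed correlation invariant, and empirically
  estimates the ρ = 0.8 Gaussian MI (0.5108 nats) with ~1% mean bias.
  The product kernel remains available as `"diagonal"`.
- *Evaluation*: the KDE is evaluated by linear binning plus FFT
  convolution with the kernel sampled on the grid — numerically the same
  estimator (binning error is far below the statistical error at the
  default grids) and ~100× faster, which is what makes the exhaustive
  band-pair MI scan feasible.
- *Normalisation*: each subject's MI edge matrix is min-max rescaled
  over its off-diagonal entries into [0,1] (NMI), the diagonal set to 0.
  An entropy-based normalisation I/√(H(X)H(Y)) would be scale-free per
  edge rather than per subject but is not the default.

MI edges carry no p-values: a permutation null for a strictly
non-negative, noise-inflated statistic would require a different
calibration than the correlation test, and the min-max normalisation
already removes the per-subject scale.

## Band-adaptive networks and thresholding

For every ROI pair the measure is scanned over unordered band
combinations (k ≤ l, band k on the lower-indexed ROI), including k = l by
default — same-band coupling is the common case, and a switch
(`include_same_band=False`) restricts to strictly different bands. Ties
break to the smallest k, then l. The scan is exhaustive:
n(n−1)/2 · a(a+1)/2 evaluations per subject, vectorised as a Gram matrix
of centred, normalised coefficient rows for CCC and as cached binned
densities for MI.

Thresholding is two-stage: CCC edges with p ≥ α (default 0.05) are
zeroed; then v_t, the t-quantile (linear interpolation) of the surviving
nonzero upper-triangle weights, removes all edges strictly below it —
a weight equal to v_t survives, so t = 0 keeps every surviving edge.
Quantiles are computed per subject, each network thresholded on its own
weight distribution; pooling thresholds across a cohort would couple
subjects' sparsity patterns. The default grid is
t ∈ {0, 0.1, …, 0.9, 0.95, 0.99}.

## Feature selection and classification

A subject's feature vector is the strict upper triangle (n(n−1)/2
values); the CCC-network block at threshold t₁ and the MI-network block
at t₂ are concatenated. Feature selection fits a boosted-tree ensemble
(200 trees, depth 3, learning rate 0.1, column subsampling 0.5) and
ranks features by total gain; column subsampling spreads importance over
correlated features instead of crediting one arbitrary member of a
redundant group. Zero-variance columns (ubiquitous after thresholding)
are dropped first. Selection is re-fit inside each outer training fold by
default, so the held-out subject never influences which features are
used; a `"global"` mode that selects once on all subjects is provided for
comparison and warns that it is optimistic.

The evaluation is nested leave-one-out: per outer fold, features are
standardised with training statistics only, the top-k (default 25)
features selected, and `n_random_draws` (default 25) hyperparameter
configurations — n_estimators ∈ {100,200,300}, max_depth ∈ {3,5,7,10},
learning_rate ∈ {0.01,0.1,0.2}, subsample and colsample ∈ {0.8,0.9,1.0},
min-split-loss ∈ {0,0.1,0.2} — are scored by inner stratified 5-fold
cross-validation (an exact inner LOO is available but quadratic in cost);
the best draw is refit and scores the held-out subject. Pooled held-out
probabilities give the confusion counts (threshold 0.5), accuracy,
precision, recall, F1, the ROC curve and the AUC (equal to the normalised
Mann–Whitney U; tied scores count ½). Trees use the exact greedy split
finder: at these sample sizes (tens of subjects) histogram binning can
place a split threshold on an extreme training value instead of the
margin midpoint, flipping boundary cases. Everything is deterministic
given the run seed, from which all per-fold seeds derive.

## Synthetic cohorts

The generator emulates the *shape* of a resting-state cohort — two
groups, n ROIs × m time points at a given TR, unit-variance background
(white or 1/f^β) — and plants dependence with known ground truth:

- *Linear edge*: both ROIs receive the same narrowband source (Gaussian
  spectral window, σ = 0.005 cycles/sample ≈ one fifth of the inter-band
  step, so the coupling is band-resolved), scaled by `strength`; strength
  s means a planted/background variance ratio of s².
- *Quadratic edge*: the target receives the band-limited 2f harmonic of
  the source's band component (A² cos 2φ). The harmonic is linearly
  uncorrelated with the source by the symmetry of the square but shares
  its envelope, so MI detects it and CCC does not; the slow envelope-
  squared baseband is deliberately excluded because it would bleed into
  the lowest analysis bands. Nonlinear sources use a wider window
  (σ = 0.01) — the dependence is carried by the envelope, which must
  vary within the record to be estimable.
- *Envelope edge*: the target carries a different-band carrier
  amplitude-modulated by the source's envelope.
- *Group-difference edges* exist only in group 1.

What the generator does **not** emulate: hemodynamic response dynamics,
physiological noise structure, head motion, spatial autocorrelation
between ROIs, or site/scanner effects. Passing tests on these cohorts
demonstrates that the estimators and the pipeline recover the kinds of
dependence they claim to measure at realistic sizes — not that any
particular clinical classification accuracy transfers to real data.

Presets: `fast_preset("strong")` is 20 ROIs, 20 + 20 subjects, 80 points
at TR = 3 s, with four shared edges and eight group-specific ones at
strength 0.8 (six linear, two quadratic) — designed so that the planted
group difference is clearly recoverable; `study_preset()` mirrors the
scale of a typical published cohort (90 ROIs, 45 + 45 subjects).

## Problem sizes and determinism

The shipped validation workloads are chosen to run on a single CPU at
desk scale: the end-to-end classification uses the 40-subject fast
preset; the nonlinear-selectivity study uses 10 subjects × 12 ROIs at
240 time points (longer records, because envelope MI needs envelope
degrees of freedom); permutation-calibration uses 200 replicates of
B = 200; the label-permutation null for the end-to-end run re-evaluates
the classifier with a slimmed search budget (3 draws, inner 3-fold),
which leaves the null distribution of accuracy essentially unchanged
while avoiding a 20-fold repetition of the full search. Every stochastic
component draws from a seed tree rooted in a single run seed.

## Known limitations

- The permutation test ignores autocorrelation under the default scheme;
  use `"circular"` when the null must respect smoothness.
- Min-max NMI normalisation guarantees one 0 and one 1 edge per subject,
  so NMI weights are only comparable within a subject.
- The band-pair scan assigns band k ≤ l with k on the lower-indexed ROI;
  a directed coupling from a high-indexed source band to a low-indexed
  target band is found at the transposed combination.
- Nested LOOCV at ~40 subjects has high variance per run; single-run
  accuracies should be read with ±1–2 subjects' worth of slack.
- KDE MI is biased upward for strongly autocorrelated (smooth) signals;
  the per-subject normalisation and the cohort-level averaging in the
  validation studies account for this, but individual low-band MI values
  should not be interpreted absolutely.
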