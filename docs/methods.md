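# Methods

This note records the models behind each stage of the cascade, the
numerical choices made where the design was open, what the synthetic
phantoms do and do not emulate, and the known limitations.

## Preprocessing

Raw rasters (GIF/JPG/PNG) are decoded with imageio, normalised by
their integer type maximum (255 or 65535), and RGB inputs collapsed
with BT.601 luminance weights (0.299, 0.587, 0.114); the source
material does not fix an RGB→gray rule, so the broadcast-television
standard is used.  Images must be 256×256; other sizes are rejected
unless bilinear resampling is explicitly requested, because silent
resizing changes the feature geometry.

Denoising defaults to the adaptive local-statistics Wiener filter:
per-pixel shrinkage toward the local window mean with gain
`max(0, s² − σ²)/max(s², σ²)`, window 3×3, reflect padding, and the
noise power σ² estimated as the mean of all local variances.  This is
the standard image-restoration practice when no blur model is
available; the textbook Fourier-domain Wiener deconvolution
`W = H* S_xx / (|H|² S_xx + S_nn)` is provided for completeness, with
"estimate" spectra derived from the periodogram minus the local-variance
noise floor.  On a constant image the adaptive filter is exactly the
identity (zero local variance everywhere); on pure noise it strictly
shrinks the variance; output is always clipped back to [0, 1].

## Wavelet features

The 1D analysis step is a periodized (circular) convolution with the
analysis taps followed by dyadic downsampling,

    cA[k] = Σ_m lo[m] x[(2k + L/2 − m) mod N],

and the 2D transform applies it separably along both axes.
Periodization is the one boundary mode in which every supported filter
bank yields exactly N/2 coefficients per level, so the level-3
approximation of a 256×256 slice is 32×32 = 1024 for every family;
symmetric extension would inflate db2/coif1 subbands and break that
fixed feature length.  Filter taps are hardcoded from closed forms
(Haar; db2 via √3; coif1 via √7).  Order-1 symlet, biorthogonal and
reverse-biorthogonal banks coincide numerically with Haar and are
implemented as aliases that keep their own names for family sweeps.
Synthesis uses the exact adjoint of the analysis operator, which for
these orthonormal taps is the inverse, so reconstruction is perfect to
machine precision and orthogonal families conserve energy (Parseval).
Subbands are named with the axis-0 filter first (LH = low along rows,
high along columns).  Features are the deepest LL subband flattened
row-major — recorded so feature files are bit-stable across runs.

## Probabilistic PCA

The latent model is `y = W x + μ + ε` with isotropic residual
`ε ~ N(0, v·I)`; marginally `y ~ N(μ, WWᵀ + v·I)`.  Maximum-likelihood
fitting uses EM.  With complete data, one thin SVD of the centred data
puts the iteration in the r = min(n, p)-dimensional eigenbasis of the
sample covariance; each sweep then costs O(p·r·k), which is what makes
k = 13 on 1024-dimensional features cheap even when refitted in every
CV fold.  With missing entries (NaN), samples are grouped by
missingness pattern and the EM treats missing values as additional
latent variables (posterior moments per pattern, per-feature
decoupled M-step).

Numerical choices: W initialised as 0.01·N(0,1) under the given seed;
v initialised to the mean per-feature variance; convergence when the
absolute log-likelihood gain falls below tol (default 1e−6), capped at
1000 iterations with a `converged` flag rather than an exception;
v floored at 1e−15 so the likelihood stays finite on exactly low-rank
data (classical PCA is the v → 0 limit).  k must satisfy
k < min(n−1, p), else v would hit zero identically and the request is
rejected.  Only the span of W is identifiable, so the returned
loadings are orthogonalised by SVD and all comparisons are made via
principal angles.  Features are mean-centred only — no unit-variance
scaling — since wavelet approximation coefficients share a common
physical scale.  The fraction of variance captured is reported as a
diagnostic (`explained_variance_ratio`), not enforced: on phantom
features 13 components hold ≈38% of the variance, and the cascade
separates the classes regardless, because the class signature
concentrates in the leading components.

## Random-subspace KNN ensemble

Each of the 30 members draws `ceil(d/2)` = 7 of the 13 latent
dimensions uniformly without replacement (independently across
members; duplicate subspaces permitted) and stores a K = 5 Euclidean
nearest-neighbour classifier.  Determinism is total: neighbours are
ordered by (distance, training index) with a stable sort, even-K vote
ties fall back to the single nearest neighbour, and the member
subspaces derive from one seeded generator.  The ensemble label is the
member majority; an ensemble-level tie is resolved to *pathological*,
operationalising the asymmetric clinical cost of a missed diagnosis.
Ensemble size, subspace dimension and K are unspecified in the source
method and are therefore configurable, with the classic
random-subspace convention as default.  Member-level instance bagging
is deliberately absent: members share the full training set and differ
only in their feature subsets.

## Cross-validation and metrics

Stratified folds are built per class: after a seeded shuffle the
class's samples are dealt round-robin onto folds, with the starting
fold rotating across classes, so per-class counts per fold and total
fold sizes both differ by at most one.  Repeats r = 0..R−1 use seeds
seed+r (R = 5 by default).  Wiener denoising and wavelet features are
deterministic per-image transforms computed once before CV; PPCA and
the ensemble are refitted inside every training fold, so no validation
information leaks into model fitting (asserted by instrumentation in
the tests).  Per-repeat accuracy pools the confusion counts of that
repeat's folds; the headline number is the mean over repeats.
Metrics with zero denominators (e.g. sensitivity without positive
cases) are returned as NaN with an explicit reason rather than raised.

## Phantom generator

Each phantom is an elliptical mask (semi-axes 108×88 px on a 256×256
grid) with a smooth radial intensity profile, plus Gaussian-smoothed
white-noise texture (smoothing σ = 3 px, amplitude 0.06) and i.i.d.
pixel noise (σ = 0.05).  Pathological phantoms add `lesion_count`
hyperintense Gaussian blobs (bright, as lesions appear on T2-weighted
contrast) of amplitude `lesion_contrast` at uniform in-mask positions.
The default class mix is 85% pathological, mirroring the deliberately
pathological-heavy composition of curated atlas collections.

The default lesion condition is a diffuse multifocal load: 25 foci of
σ = 24 px at amplitude 0.15.  This choice is structural, not cosmetic.
A phantom class defined by a few small blobs at random positions is
*not* learnable by this cascade: the blobs add class-specific variance
with no consistent signature, and in latent space every held-out
pathological sample sits closer to the compact normal cluster than to
the dispersed pathological one, driving a distance-based classifier to
systematic false negatives.  With many broad overlapping foci the
aggregate lesion field concentrates around its mean (the shift grows
with count², the positional variance only with count), giving the
classes a consistent global signature — the analogue of the conspicuous,
spatially extensive hyperintensity of real pathological slices.  Under
this condition the end-to-end 5×5-fold accuracy on 60 balanced
phantoms is ≥98% across seeds, and at zero contrast (classes
exchangeable by construction) it sits in the binomial band around 50%.

What passing phantom tests shows: the plumbing, determinism, fold
hygiene and the cascade's ability to pick up a genuine global
intensity signature at realistic noise levels.  What it does not show:
performance on real anatomy — phantoms have no gyri, ventricles,
skull, partial-volume effects, bias fields, or disease-specific lesion
morphology, and real "normal" inter-subject variability is far richer
than smoothed noise.  Published accuracies on clinical atlas data are
therefore not reproduced here.

## Problem sizes

Default exercises are sized for a single CPU: 60-image phantom sets
for end-to-end cross-validation (25–50 PPCA+ensemble fits), n = 2000
draws for the PPCA recovery study, and 64×64 images for transform
round-trip tests.  All are package choices and scale linearly if
enlarged.

## Known limitations

- Only two-class problems; multi-disease discrimination is out of scope.
- The frequency-domain Wiener mode estimates spectra crudely
  (periodogram minus noise floor) and is intended for known-H
  deconvolution demonstrations, not blind restoration.
- The missing-data EM loops over missingness patterns; it is meant for
  moderate n·p (thousands), not for massively incomplete matrices.
- KNN stores the entire training fold; memory grows linearly with
  training size, acceptable at the few-hundred-image scale this
  package targets.
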