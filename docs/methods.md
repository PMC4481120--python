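# Methods

## The measurement model

A replicated landmark study digitizes K anatomical landmarks on n
individuals with M methods, t replicates per individual per method.
Each digitization (a *configuration*) lives in its own coordinate
frame: a digitizer arm defines axes relative to an arbitrary reference,
and CT-derived coordinates are voxel indices until multiplied by the
scan's mm-per-voxel resolution. The package models a configuration as

X(i, m, t) = frame( S_i + b_m + E(i, m, t) )

where S_i is individual i's true landmark geometry (mm), b_m a fixed
per-landmark bias of method m, E independent per-landmark digitizing
error, and frame(·) an arbitrary rigid motion. All analyses are
invariant to frame(·) by construction: Procrustes superimposition
removes location, size and orientation before landmark deviations are
measured, and inter-landmark distances are rigid invariants.

## Generalized Procrustes Analysis

`gpa` centres every configuration, scales it to unit centroid size
(CS = root summed squared deviation from the centroid), seeds the mean
with the first configuration's orientation, and iterates: fit each
configuration's least-squares proper rotation onto the current mean
(Kabsch/SVD, reflections repaired by flipping the smallest singular
axis — anatomical shapes must never be mirrored), then replace the
mean by the renormalized average. Iteration stops when the RMS change
of the mean drops below `tol` (default 1e-10; `max_iter` 100 — landmark
data converge in a handful of iterations, though mutually dissimilar
random shapes can need more). The fitted per-configuration similarity
transform (translation = centroid, scale = centroid size, rotation) is
stored so additional points can be mapped into shape space.

Numerical notes: a rank-deficient cross-covariance (collinear
landmarks) makes the rotation non-identifiable and raises; the GPA
objective is monitored against the renormalized mean, where the
renormalization can in principle move it by machine-precision amounts
even though both alternating steps are non-increasing.

## Leave-one-landmark-out precision

A landmark's precision is estimated with that landmark excluded from
the superimposition: GPA runs on the remaining K−1 landmarks, the
held-out landmark of each configuration is mapped with its
configuration's *full* similarity transform, and the deviation is the
distance to the mean of the mapped held-out points. Applying the full
transform (not the rotation alone) is a deliberate choice: without the
centring and scaling of the reduced configuration the held-out point
does not live in the shared shape-space coordinate system, so
rotation-only application is geometrically incoherent. The procedure
repeats for every landmark; with a bilateral protocol only the midline
and left-side landmarks are analysed by default (one instance per
landmark). Deviations are converted to mm by the mean centroid size of
the analysed landmark subset, so the mm rescaling is exactly linear.

Replicates enter as independent configurations and deviations are
pooled across all configurations of a method; duplicating every
configuration therefore changes nothing.

**What the estimator does and does not buy.** Excluding the landmark
removes the fit's shrinkage of its own residual (fitted residuals obey
E‖res‖² ∝ (1−h), held-out predictions (1+h), with h the landmark's
leverage), so the LOO estimate of a highly variable landmark is not
pulled down and the most variable landmark is identified essentially
always in simulations (5× inflated error: 100/100 runs). It does *not*
decontaminate the estimates of the other landmarks — the variable
landmark still sits inside their K−1-point fits — and because the
plain-GPA estimator's shrinkage both offsets its spreading bias and
reduces its variance, the plain estimator's *profile* across landmarks
can be as close or closer to the true error-scale profile at small n.
The LOO estimator's advantage is localization and unshrunk per-landmark
magnitude, not profile mean-absolute-error.

## Repeatability from variance components

One-way ANOVA with individuals as groups: s² = MS_within,
s²_A = (MS_among − MS_within)/k₀, with k₀ the group size (or the
standard effective size (N − Σnᵢ²/N)/(a−1) for unbalanced data, which
is flagged), and r = s²_A/(s² + s²_A). Negative s²_A estimates are
clipped to zero (keeping r ∈ [0,1]); the raw value is retained. r is
defined as 0 when both components vanish. Between-method repeatability
pools the two methods' replicates per individual, restricted to the
individuals measured by both so the design stays balanced; a fixed
method bias shifts every individual equally, leaving MS_among alone and
inflating MS_within by δ²_d per group (δ_d the distance-level bias
difference) — the mechanism of the between-method drop.

## Differences and the length correlation

Raw differences are first-listed minus second (replicate 1 − replicate
2; method A − method B on per-individual replicate means — the mean is
used rather than a single replicate to halve noise; a flag selects
replicate 1 only). Percentages divide each distance's mean absolute
difference by that distance's mean over the data involved; summary
percentages average the per-distance percentages, not the ratio of
summary means. The repeatability-versus-length association uses the
Pearson product-moment correlation with a two-sided t test on n−2
degrees of freedom at α = 0.05.

## Quality control

Within-method replicate pairs are compared per distance against 0.5 mm,
or 0.3 mm for distances whose observed method-wise mean is below
3.0 mm (an explicit id list can override the data-driven rule, since
published small-distance sets are sometimes fixed by protocol). QC is
report-only: gross errors are human errors to be re-measured, not data
to be silently dropped.

## The synthetic generator

`simulate_dataset` emulates the reference design: 20 individuals, 2
replicates, three methods — DIG (digitizer, mm, per-landmark error SD
0.20 mm) and MED/HIGH (CT, voxel units at 0.01742 / 0.00871 mm per
voxel, error SDs 0.11 / 0.10 mm). The error SDs were back-solved from
reported mm deviation ranges of comparable instruments via the mean of
the 3-dof chi distribution (E‖N₃(0, σ²I)‖ ≈ 1.596 σ). Individuals get
per-coordinate Gaussian shape jitter (0.15 mm) and a size factor with
8 % CV — size variation is what makes among-individual distance
variance grow with distance length, and hence repeatability correlate
with length once an mm-scale error floor exists. Each digitization
receives a random rotation and translation (`rigid_nuisance`); an
optional per-frame *scale* distortion exists only to exercise the full
similarity invariance of GPA and is off by default, because a
calibrated instrument does not rescale real distances (with it on,
raw-distance repeatability is destroyed by design).

`expected_repeatability` propagates coordinate-level variances to each
distance by the delta method along the inter-landmark direction
(bilateral averaging and midline-shared endpoints handled through the
summed gradient), adds the size-variation term (CV × distance)², and
returns σ²_ind,d/(σ²_ind,d + σ²_err,d). It refuses biased methods (the
decomposition no longer holds) and is first-order: for error SDs above
~5 % of a distance's length the prediction can deviate by a few
hundredths.

**What passing tests do and do not show.** The generator's errors are
Gaussian, independent across landmarks and replicates, and isotropic
per landmark; real digitizing error is anisotropic (along sutures),
spatially correlated (frame drift of a digitizer arm), and
occasionally grossly wrong (the QC rule exists for a reason; a
heavy-tailed option exercises it). Published data of this kind also
show an internal tension the independent-error model cannot produce:
landmark-level deviations imply per-landmark errors around 0.2 mm
while replicate distance differences imply ~0.08 mm, which is
consistent with a correlated per-configuration component that cancels
in distances. The defaults calibrate to the landmark-deviation scale;
simulated within-method repeatabilities are correspondingly somewhat
lower (≈ 0.6–0.9) than the ≈ 0.94–0.98 such studies report.

## Problem sizes

Module tests run on small designs (4–20 individuals); the recovery,
localization, degradation and correlation checks use 20–100 seeded
replications at the designs stated in each test (up to 200 individuals
for variance-ratio recovery, 1000 for the delta-method check), sizes
chosen to bound Monte-Carlo error well below the asserted tolerances.

## Known limitations

- Missing landmarks exclude a configuration from GPA-based analyses
  (no imputation); distances through a masked landmark are masked.
- The unbalanced-design path (k₀) is provided but flagged; the
  reference design is balanced.
- TPS input carries no method/replicate metadata; the caller supplies
  both.
- `expected_repeatability` is undefined under method bias, by design.
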