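# Methods

This note documents the models, estimators, numerical choices and known
limitations of `oisi`.  It is the design record a maintainer should read
before changing a default.

## Signal model and synthetic data

The generator emulates one intrinsic-signal imaging session: for every eye
(contralateral / ipsilateral to the imaged hemisphere) and every spatial
frequency (SF) of the stimulus protocol, a stack of `n_repeats` trials ×
5 frames × 32 × 32 pixels.  Frame f of a trial is

    R0 · (1 − w_f · T(sf, eye) · P(y, x)) · (1 + d_f) + v(y, x) + n_f(y, x)

- **Baseline** R0 = 1 (all noise SDs are fractions of baseline reflectance).
- **Hemodynamic weights** w = (0, 0.5, 1, 1, 1): the first stored frame
  precedes the response, the last three carry the full signal.  Any weight
  vector with w_0 = 0 and positive last three is accepted; the time course
  between those constraints is not otherwise modeled.
- **Tuning** T is piecewise linear in log10(SF): the response amplitude A up
  to `peak_sf_cpd`, a straight limb from A down to exactly 0 at
  `acuity_cpd`, 0 beyond.  This makes the acuity analytically identifiable
  by the pipeline's own estimator (a line fitted in log10-SF coordinates has
  its x-intercept exactly at the true cutoff), so noiseless recovery
  failures indicate bugs, not model mismatch.  Defaults: contra A = 2e-3,
  acuity 0.5 cpd; ipsi A = 1.4e-3, acuity 0.35 cpd; peak at the lowest
  tested SF.  Fractional reflectance changes of 1–3 × 10⁻³ are the
  magnitude this preparation produces.  Exactness of the noiseless
  x-intercept additionally requires the descending limb to dominate the
  fitted segment: with the default 0.05 segment-stop floor that holds when
  the plateau occupies a single grid point and the first sub-floor sample
  lies on the limb (or the cutoff coincides with a grid point); the shipped
  default acuities satisfy this.
- **Spatial profile** P: 1 inside an elliptical binocular zone (semi-axes
  7 × 5 px), cosine taper over 2 px of elliptical radius, 0 outside.
- **Noise**: (i) per-pixel, per-frame white noise, SD 2e-3; (ii) a
  vascular-like pattern per trial — white noise smoothed with an anisotropic
  Gaussian (SD 3 px, 3:1 aspect), rescaled to SD 5e-4, constant across the
  frames of a trial; (iii) global multiplicative drift, a per-frame AR(1)
  scalar with marginal SD 2e-3 and persistence ρ = 0.98.  The drift models
  slow vasomotion (~0.1 Hz): consecutive 1 s frames are strongly
  correlated, and only the residual frame-to-frame decorrelation survives
  the frame ratio (per-trial ratio offset ≈ 0.31 × SD).  Orientation and
  direction variants of the grating are folded into the repeats and not
  modeled as separate dimensions, since the analysis averages across them.

**Grid size.** The default field is 32 × 32 px at 84 µm/px (a ~2.7 mm
field, the scale of the imaged region, at reduced resolution).  This is a
deliberate operating-point choice: the white component of the generator's
noise is independent per pixel, so the residual ensemble's effective
spatial dimensionality equals the pixel count.  Covariance-based pattern
extraction needs that dimensionality to be comparable to the number of
trials (320 per session); at 32 × 32 the stimulus-locked component separates
cleanly from sampling noise, while at 64 × 64 (4096 dimensions) no
covariance estimate from 320 trials can.  Real recordings are far larger in
pixels but their noise is optically and physiologically correlated, so the
pixel count greatly overstates their effective dimensionality; the coarse
grid is the honest equivalent regime, not a cosmetic down-scaling.

**What passing tests do and do not show.**  The generator reproduces the
statistical structure the analysis assumes — a multiplicative dip confined
to a compact zone, a silent first frame, structured plus white noise.  It
does not emulate photon/camera noise, motion, breathing artifacts,
vessel-specific dynamics, retinotopic structure within the zone, or
orientation-dependent responses.  Parameter recovery here therefore
validates the *analysis*, not the acquisition.

## Preprocessing

Per-trial response map = mean(last three frames) / first frame, computed
per pixel; the count of response frames is fixed at three (override
explicit).  Division uses the trial's own first frame.  Maps carry a stage
tag (`raw_ratio` → `denoised` → `smoothed`) and a value scale (`ratio`,
magnitude |1 − value|; or `magnitude`, |value|), so downstream stages are
scale-aware.  Spatial binning averages complete factor × factor blocks and
crops trailing rows/columns — padding would fabricate reflectance values.
The generator emits stacks at the post-binning scale of the acquisition
(the camera stores 2 × 2-binned images), so the pipeline's default bin
factor is 1.

## Indicator-function denoising

Construction: the **signal ensemble** is the condition-mean maps (one per
eye × SF, 20 in the default protocol); the **noise ensemble** is the
per-trial residuals (trial map minus its condition mean).  With C_S and C_N
their pixel covariances (each ensemble centered), the generalized
eigenproblem C_S v = λ(C_N + εI)v is solved exactly; λ is the ratio of
stimulus-locked to residual variance along v.

- **Solver.**  When both ensembles have fewer samples than pixels the
  problem is solved in snapshot space: M = C_N + εI is whitened through the
  SVD of the residual matrix (Woodbury form of M^(−1/2)), and the whitened
  signal covariance — rank-bounded by the signal snapshot count — is
  diagonalized in that small space.  The solution is exact, not
  approximate: every retained pair satisfies the pixel-space pencil with
  relative residual ≤ 1e-6 (asserted in tests), and matches a direct dense
  `scipy.linalg.eigh` solve to 1e-8 on problems small enough to run both.
- **Ridge.**  ε = trace(C_N)/n_pixels — the mean per-pixel residual
  variance.  A much smaller ridge (say 1e-6 × that) makes the metric
  near-singular off the residual sample span whenever residual samples <
  pixels; the eigensolver then finds directions whose Rayleigh quotient
  divides by ~ε alone and manufactures arbitrarily large spurious
  eigenvalues.  With the noise-floor ridge, directions the residuals never
  sampled are charged the average noise variance.  ε reverts to an absolute
  floor of 1e-12 only if the residuals are identically zero.
- **Retention.**  `gif_fit`'s default keeps λ > 1 (more stimulus-locked
  than residual variance).  The pipeline calibrates that threshold against
  a **permutation null**: trials are randomly reassigned to pseudo-conditions
  of the same sizes, pseudo condition means and residuals are refit, and
  the largest null eigenvalue (maximum over 3 shuffles, floored at 1) is
  used as the threshold.  This matters because sample covariances of 20
  snapshots in ~1000 dimensions concentrate noise power into their few
  sample directions, inflating even noise-only eigenvalues well above 1; a
  fixed λ > 1 rule would then retain everything and the filter would reduce
  to the identity.  The null reduces to the λ > 1 rule on clean data and is
  seeded from the run seed.  A fixed threshold remains available
  (`retain_rule="fixed"`).
- **Filtering.**  Generalized eigenvectors are spatial *filters*; the
  corresponding activation patterns a = Mv (biorthogonal to the filters,
  living in the range of C_S) are what a component looks like in the image.
  A map is denoised as mean + Σ a_k (v_kᵀ (map − mean)): coefficients read
  out by the filters, image rebuilt from the patterns.  This oblique
  projection is idempotent, reproduces any map in the retained activation
  span exactly, and — unlike the M-orthogonal projection onto the filter
  span — does not warp the signal through M^(−1).
- **Smoothing.**  Normalized 2-D Gaussian, SD 3 px, reflect boundary
  (preserves constants; no fabricated zeros at the field edge).

## ROI, tuning and acuity

The binocular zone is delineated from the low-SF (three lowest) smoothed
maps of the ipsilateral eye: z-score the mean magnitude map over pixels,
threshold at z ≥ 2, keep the largest connected component, fill holes; a
manual mask overrides detection.  ROIs under 25 px are rejected.  Because
every stage up to the tuning curve is linear in the response and the same
ROI serves all conditions, the recovered curve is proportional to the true
tuning regardless of the exact ROI — ROI choice moves curve *scale*, which
normalization removes (a 2 px dilation changes noiseless acuity by far less
than half a grid step; asserted in tests).

Tuning magnitude per SF = ROI mean of the stage-appropriate magnitude.
After normalization by the maximum across SFs, the acuity fit: peak index =
argmax (ties toward the lowest SF, keeping the descending limb maximal);
segment runs from the peak through the first point at or below the noise
floor (default 0.05 normalized units), or through the last SF if none; OLS
of magnitude on log10(SF); acuity = 10^(−intercept/slope).  Fits with
non-negative slope or fewer than two segment points are errors; an
x-intercept beyond the highest tested SF is reported but flagged
**censored**, and cohort comparisons clamp censored values to that bound
rather than extrapolating.  The log10 fit domain matches the log-spaced
stimulus design (a linear-cpd integration/fit option is config-exposed).
Known bias of the segment rule: when the response floor sits *above* the
noise floor, the segment extends across the post-cutoff tail and the
intercept inflates to the right; this is visible at low true acuities under
default noise and is the dominant error term there (the median error stays
well inside one grid step, the tail does not).

## Ocular dominance

Per-eye response integrals are trapezoidal in log10(SF), restricted to
SF ≥ threshold — each threshold's index summarizes the high-SF tail, which
is what lets the profile localize a dominance shift to frequencies above a
given value.  Integrals use **un-normalized** magnitudes (per-eye
normalization would erase the between-eye contrast being measured).
ODI = (C − I)/(C + I), in [−1, 1]; thresholds where both integrals vanish
are reported as undefined rather than 0.

## Expression quantification

2^−ΔΔCt with technical replicates collapsed at the Ct level before ΔCt
(averaging fold changes instead is a one-line change and intentionally not
the default); percent-of-control = 100 × value / control mean, summarized
as mean ± SEM (SEM omitted at n = 1); the pairwise test is the classical
pooled-variance Student t (Welch is deliberately not used).  Degenerate
zero-variance inputs return t = 0, p = 1 for equal means and an infinite
statistic with the smallest positive double as p otherwise.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed reproduce reports
byte-for-byte.  Shipped validation sizes: 10 SFs × 2 eyes × 16 trials on the
32 × 32 grid (~0.4 s per full pipeline run); stochastic recovery checks use
20 seeds per condition and cohort comparisons 5 simulated animals per
group — sizes at which the test suite demonstrates the statistical
properties while each property remains re-runnable in seconds to a few
minutes.

## Known limitations

- The indicator-function stage assumes condition-mean and residual
  ensembles share the noise subspace; slow nonstationarities across a
  session (not simulated) would violate this.
- The acuity estimator's segment rule is deterministic but floor-sensitive
  (see above); with very few points past the peak the OLS variance grows.
- The permutation null uses 3 shuffles for speed; its threshold is
  therefore itself noisy by a few percent, which only matters for
  components sitting exactly at the null level.
- Cell counting, stimulus rendering, eccentricity correction and
  acquisition control are out of scope; counts and Ct values enter as
  tables.
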