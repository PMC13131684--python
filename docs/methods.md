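# Methods

This note documents the models and procedures implemented in `mveks`, the
defaults and why they were chosen, the numerical details, and what the
synthetic-data experiments do and do not establish.

## State-space model

Each keypoint is smoothed independently. The stacked per-view pixel
observations x_t ∈ ℝ^2V are modeled as projections of a latent z_t with
random-walk dynamics:

- dynamics: z_t | z_{t−1} ~ N(z_{t−1}, s E), with E a fixed d×d process
  covariance and s > 0 a per-keypoint smoothing scalar;
- linear observations: x_t | z_t ~ N(W z_t + μ_x, D_t);
- nonlinear observations (per view j): x_t^j | z_t ~ N(f_j(z_t), D_t^j),
  where f_j is the calibrated camera projection and z_t is a 3D world
  point.

D_t is diagonal, holding the per-coordinate ensemble variances; it varies
per frame, which is what lets ensemble disagreement (and the inflation
procedure below) modulate the smoother's trust in each observation.

### Initialization (linear)

- Frames used for PCA: fully valid frames whose maximum ensemble variance
  across views/coordinates falls below the 50th percentile
  (`low_var_quantile`, configurable). The threshold is a package choice —
  "low ensemble variance" needs an operational definition.
- μ_x = mean of the selected observations; W = top-d principal directions
  scaled by the per-component standard deviations, so the latent is
  approximately whitened. Default d = 3: the stacked multi-view
  observations of one body part are projections of a single 3D point, and
  synthetic narrow-field scenes confirm > 99 % of variance in 3 components.
- E = covariance of first differences of the PCA projections over
  consecutive valid frames; E is time-invariant (a single estimate), with
  the time-varying hook left to future work.
- s is initialized at the mean (across latent dimensions) of the standard
  deviations of those projected first differences, which empirically lies
  near the likelihood optimum; the scalar reduction (mean of per-dimension
  standard deviations) is a package choice.
- Initial state prior: mean = generalized-least-squares estimate from the
  first valid frame, covariance = 10 E (a weakly informative prior; the
  model is insensitive to the factor once a few frames are filtered).

### Initialization (nonlinear)

The 3D analogue of the above, in world units: the per-frame observations
are triangulated (DLT over all camera pairs, averaged), E is the
covariance of first differences of the triangulated track, s starts at the
mean per-axis standard deviation of those differences, and the initial
state is the first triangulable frame with covariance 10 E.

### Recursions

Linear mode runs a standard Kalman filter plus Rauch–Tung–Striebel
smoother; the marginal log-likelihood is accumulated from the filter
innovations. Nonlinear mode runs an extended Kalman filter with analytic
Jacobians of the full projection chain (extrinsics, perspective division,
radial + tangential distortion, intrinsics), validated against central
differences in the tests. The dynamics are linear, so RTS smoothing is
exact given the filtered moments. Each EKF update performs one iterated
relinearization about the posterior mean (an IEKF step); this removes the
leading-order linearization error and is what makes noiseless synthetic
trajectories recover to ~1e−5 world units instead of ~3e−4.

Missing or invalid observations are handled by setting their variance to
1e12 px² rather than resizing the recursion; ensemble variances are floored
at 1e−10 px² so exactly-zero-variance (degenerate synthetic) inputs remain
well-posed. Non-positive-definite intermediate covariances are symmetrized
and jittered (logged at debug level).

### Smoothing-parameter selection

s is optimized in log-space (guaranteeing positivity) by Adam with
learning rate 0.25 on the filter's marginal log-likelihood; gradients are
central finite differences (ε = 1e−3 in log s). Convergence: 100
iterations maximum, |Δ log s| < 1e−4, or 15 iterations without
improvement. Non-finite evaluations reject the step and halve the step
scale. The best evaluated point is returned, so the final likelihood never
falls below the initial one. On data simulated from the generative model
(T = 1000), the estimate lands within a factor of two of the generating
value and the likelihood curve over a 50-point log-spaced grid is unimodal
(both asserted in the acceptance tests).

## Cross-view inconsistency and variance inflation

The per-view inconsistency score uses the factor-analysis form of the
observation model with an uninformative latent prior: B = (Wᵀ D⁻¹ W)⁻¹.
For view v, B and the latent posterior mean are computed from the
*remaining* views only (leave-one-out); the predicted observation is
x′_v = W_v μ_{z|x₋ᵥ} + μ_x,v with covariance Q_v = D_v + W_v B₋ᵥ W_vᵀ, and

    d_v = sqrt( (x_v − x′_v)ᵀ Q_v⁻¹ (x_v − x′_v) ).

Design choices worth stating:

- **Root scale.** d_v is the square root of the quadratic form — the
  multi-dimensional analogue of a z-score — and the threshold 5 applies on
  that scale (i.e. a 5-sigma outlier).
- **Leave-one-out B.** Using B from the remaining views makes x′_v and the
  W_v B W_vᵀ term independent of D_v, so inflating D_v strictly grows Q_v
  and strictly shrinks d_v: the per-view inner loop is monotone and
  terminates. It also matches the score's meaning — "what do the *other*
  views predict here".
- **Sweep structure.** Views are processed in fixed rig order; an
  offending view is inflated (×10 per round) until its own distance drops
  below 5, then the next view is examined with the updated variances;
  sweeps repeat until a full pass changes nothing. Processing each view to
  convergence is what prevents mutual escalation: once the truly wrong
  view is down-weighted, the other views' leave-one-out predictions become
  consistent and they are never touched. Convergence-state results are
  order-independent in the tested scenarios.
- **Two views.** With V = 2 the wrong view is unidentifiable, so both
  views are inflated together whenever either distance exceeds threshold.
  The leave-one-out system is rank-deficient for d > 2 with two views; a
  rank-deficient system reports distance 0 and the view is skipped
  (logged), so two-view rigs should use a latent dimension ≤ 2 for the
  inconsistency score.
- **Cap.** 25 rounds per view (×10²⁵ effectively deletes an observation);
  capped entries are flagged `unresolved` in the report, never raised.
- **Nonlinear pipeline.** The same machinery is applied with W taken as
  the per-frame Jacobian of the camera projections about the triangulated
  observation (and μ_x the matching affinization), i.e. a local linear
  model per frame.

Two regimes follow from the score's structure, both exercised in the
acceptance tests: when the confidently-wrong view's inconsistency exceeds
threshold, inflation down-weights it and the smoothed estimate recovers;
when the remaining views are too uncertain to convict it, the procedure
instead inflates whatever is inconsistent and the posterior predictive
variance rises — the error is flagged rather than silently propagated.

## Geometry

Cameras are standard pinhole models with distortion coefficients in the
order k1 k2 p1 p2 k3 (the calibration-file ordering is a documented
package convention). Pixel convention: x = column, y = row, origin
top-left, subpixel values at pixel centers. Undistortion inverts the
distortion polynomial by fixed-point iteration (20 iterations, tolerance
1e−8 normalized units; non-convergence flags the point invalid), accurate
to < 1e−6 px for |k1| ≤ 0.3, |k2| ≤ 0.1, |p1|, |p2| ≤ 0.01. Triangulation
is the homogeneous DLT on undistorted normalized rays (distortion breaks
the linear DLT model, so intrinsics are stripped first), averaged without
weighting over all camera pairs; degenerate pairs (coincident rays,
singular-value ratio < 1e−9) are excluded.

## Training-side operators

- **Soft argmax**: spatial softmax with weights exp(τ·h), then spatial
  expectation; inference default τ = 1000, which collapses onto the global
  maximum. Since that localizes only to the grid, an optional bicubic
  upsampling factor (off by default) provides subpixel precision of about
  1/(2·upsample) px. Confidence = softmax mass within radius r = 3 heatmap
  pixels of the expectation (r configurable; the choice of 3 covers ±2σ of
  the default label Gaussian).
- **Density mean** (`heatmap_expectation`): expectation of h/Σh, the
  differentiable coordinate estimate used inside the reprojection loss.
  The maps entering that loss are already normalized (the network head's
  softmax), and the density mean inverts a Gaussian bump to ~1e−5 px,
  which is what makes the loss exactly zero on geometrically consistent
  scenes. The τ-softmax peak extractor and the density mean are distinct
  operators with distinct jobs; conflating them cannot satisfy both the
  peak-suppression and the subpixel contracts at once.
- **Gaussian label heatmaps**: σ = 1.25 heatmap pixels by default, grid at
  1/4 image resolution with an explicit grid→image scale carried on every
  stack. Centers far outside the grid yield near-zero maps that downstream
  consumers treat as missing.
- **Reprojection loss**: density-mean coordinates → image pixels →
  pairwise-mean triangulation → reprojection → regenerated Gaussian maps →
  MSE × (h·w), averaged over valid keypoints and views; keypoints with
  < 2 valid views are excluded. The h·w scaling keeps the loss on the same
  scale as a per-pixel heatmap MSE. The loss weight is exposed as raw
  configuration with no default (its mapping to any particular training
  configuration is trainer-specific).
- **Patch-mask curriculum**: fraction 0 before iteration 700, then linear
  from 10 % to 50 % at iteration 5000, constant after. Masks are unions of
  random rectangles with side lengths uniform on 1..4 patches ("contiguous"
  is the contract; the block-size law is a package choice), placed until
  the target fraction is reached (overshoot at most one block).
- **3D augmentation**: triangulate labels, scale by one scalar draw
  U(0.8, 1.2) about the per-axis median, shift each axis by
  U(−0.25, 0.25) × that axis's bounding-box width, reproject; per-view
  4-DOF similarity transforms (for warping images) are fitted by linear
  least squares in closed form. Untriangulable keypoints pass through
  unchanged. The non-geometric 2D augmentation list used by image
  trainers configures an external image pipeline and defines no numeric
  computation, so it is out of scope here.

## Pseudo-label selection

Stage 1 ranks frames by σ²_max — the maximum predictive variance across
keypoints, views *and* coordinates (the coordinate max is a package
choice) — and keeps the lowest 60 % (floor(keep_fraction·N), ties broken
by earlier frame index). The default quality signal is the leave-one-out
factor-model predictive variance Q (with inflated D); the smoother's
posterior predictive variance is available via `variance_source=
"posterior"`. Q is the default because it reflects cross-view agreement
directly and is what the inflation procedure calibrates. Stage 2 builds a
pose vector per frame (concatenated triangulated 3D keypoints, or PCA
scores without calibration; untriangulable keypoints imputed by the frame's
centroid of valid keypoints and flagged), clusters with k-means (k = 3000
default, lowered with a log message when fewer frames survive; Lloyd with
k-means++ seeding, 10 restarts, fixed seed), and keeps the frame nearest
each centroid. Export writes per-view label CSVs in the standard
three-row-header dialect, coordinates = smoothed posterior means,
round-tripping bit-exactly.

## Synthetic scenes

The generator emulates exactly the generative assumptions above plus the
failure modes the inflation procedure targets. A latent center random-walks
with covariance s_true·E_true (defaults s_true = 1, E_true = 0.02² I world
units² — a slow, smooth trajectory a few percent of the rig radius per
step); keypoints are a rigid constellation of fixed random offsets within
±0.5 world units (articulated skeletons are deliberately out of scope — a
rigid constellation exercises every consumer); cameras sit on a circle of
radius 5 looking at the origin (focal 300 px, image 640×480; a narrow-field
regime uses radius 100 / focal 20000); ensembles default to M = 3 members
(the ensemble size of the workflows this emulates) with i.i.d. Gaussian
pixel noise, σ_obs = 3 px by default, optionally heteroscedastic via a
log-normal per-entry scale. "Confidently wrong" segments replace all
members' predictions in a (view, keypoint, frame-range) block by a common
displaced value with 0.01 px member spread — small enough that the
ensemble variance is misleadingly confident; the uncorrelated variant uses
independent large noise instead.

What passing these tests shows: the estimators are correct implementations
of their models, the inflation logic detects and repairs (or flags) the
cross-view failure mode it was designed for, and the selection pipeline
prefers genuinely consistent frames. What it does not show: performance on
real video, where observation errors are non-Gaussian and temporally
correlated, keypoints articulate, calibration is imperfect, and ensemble
variance misbehaves in richer ways than the two corruption modes modeled
here.

## Problem sizes

The simulation-backed checks run at T = 150–2000 frames, 2–6 views, 1–2
keypoints and 20 seeds per claim — sizes at which every effect under test
(oracle equivalence, parameter recovery within a factor of two, inflation
efficacy, error orderings) is comfortably resolved on a single CPU in a
few minutes.

## Known limitations

- E is time-invariant; s is a single scalar per keypoint. Regime switches
  (e.g. movement vs. rest) are averaged over.
- The inflation sweep's order-independence at convergence is verified
  empirically, not proved, for V ≥ 3 interacting views.
- Two-view rigs cannot identify which view is wrong; both are inflated,
  which flags but cannot repair the error.
- The nonlinear pipeline linearizes about triangulated observations for
  the inconsistency score; with gross corruption the linearization point
  itself is biased (the score remains large in practice, which is what the
  procedure needs, but the distance is then approximate).
- Likelihood optimization is local (single start at the data-driven
  initialization); the unimodality observed across synthetic conditions is
  not a guarantee for arbitrary data.
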