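# Methods

## The measurement and its bias

Single-molecule displacement mapping (SMdM) estimates local diffusion
coefficients from the planar distances a molecule travels between two
stroboscopic laser pulses separated by a fixed lag (1.5 ms here). For free 2D
Brownian motion the displacement length r is Rayleigh-distributed,

    p(r | D, t) = (2r / 4Dt) exp(-r^2 / 4Dt),

whose maximum-likelihood estimate is the closed form D = Σr² / (4 n t). In a
bacterium two effects bias this estimate downward: reflections at the cell
wall shorten observed displacements, and the camera records only the xy
projection of a 3D walk that is itself confined along z. Both effects grow
with D (the walk probes more of the boundary within the lag) and are
strongest in the cap (pole) regions. In the reference geometry used
throughout — a spherocylinder of total length 2.25 μm and width 0.9 μm, the
average cell size — the apparent/true ratio in the centermost 100 nm pixel is
≈0.9 at D = 10 μm²/s, and the pooled pole regions reach a similar level
around D ≈ 1–2 μm²/s.

## Cell detection as billiard fitting

A field of view is binned into a 2D histogram (default 100 nm bins, matching
the analysis pixel); the background level is the median bin count and points
in bins above median + 1 SD (SD over all bins) are kept. 8-connected
above-threshold bins define point clouds. Each cloud is rotated to its
principal axis (covariance eigenvectors) and an initial billiard — the 2D
stadium outline of a spherocylinder — is taken from the rotated extents. The
fit is refined by maximizing, over center, length, radius and orientation,

    Σ_i log p_i,   p_i = ( h_i / V + 1/N ) / 2,

where h_i is the thickness (z-chord) of the candidate spherocylinder at
point i, V its volume and N the cloud size: each localization is equally
likely to be signal (density ∝ thickness; h/V integrates to 1 over the
outline) or noise (uniform over the N points). Optimization is bounded
L-BFGS-B (length ∈ [0.3, 6] μm, radius ∈ [0.15, 1] μm) with a small
multi-start (±10% in size) to avoid local optima.

Fits shorter than 0.65 μm or wider than 1.5 μm are flagged for discard;
fits longer than 3 μm are re-fitted as a dividing pair: two half-length
billiards optimized jointly under

    p_i = ( (h_{i,1} + h_{i,2}) / (V_1 + V_2 + V_int) + 1/N ) / 2,

where V_int is the lens volume of the two adjacent cap spheres. The line
through the cap-circle intersection points defines the septum; the caps
facing it are labelled new poles, the distal caps old poles. Pairs whose
total fitted length remains below 3 μm are flagged as mis-identified.
Manual visual QC is replaced by machine-readable flags.

## Displacement pairing and the in-vivo PDF

Within one cell, every peak in the first frame of a stroboscopic couple is
matched with all peaks within 600 nm in the second frame; ambiguous matches
are kept deliberately. Cells with fewer than 2000 or more than 20000
displacements are discarded. Displacements are binned by their start point
into a 100 nm × 100 nm grid anchored at the billiard center (half-open
intervals), and each pixel with ≥ 10 displacements is fitted with the
truncated Rayleigh-plus-background density

    p(r, t) = [ (2r/4Dt) e^{-r²/4Dt} + k r ] /
              [ 1 - e^{-r_max²/4Dt} + k r_max²/2 ],   0 ≤ r ≤ r_max,

with the truncation radius identified with the 600 nm pairing cutoff. The
linear term k·r absorbs uniform-in-area spurious pairs; the denominator
makes p integrate to 1 on [0, r_max] for any parameter values (verified by
quadrature in the tests). The (D, k) likelihood can trap a single descent at
the k = 0 boundary when the moment start is contaminated by background, so
the fit is multi-started from the moment estimate with k = 0 and from a
median-based D (robust to contamination) with 5% and 20% background mass.
Pure simulation benchmarks use the background-free form and its closed-form
MLE. Region-level estimates pool all displacements starting in the pole cap
half-disks (beyond the cap-center abscissae) or the central section.

## Forward simulation

The Brownian simulator advances particles with Gaussian per-axis increments
of variance 2·D·dt (dt = 0.1 ms) inside the capsule; segments crossing the
wall are folded back by exact specular reflection. The compartment (capsule,
optionally cut by a septum half-space) is convex, so each leg crosses the
boundary at most once; the crossing is solved analytically against the
cylinder, the two cap spheres and the septum plane, with a bisection
fallback for degenerate roundoff cases, capped at 100 bounces. Path length
is preserved exactly. Stroboscopic sampling reads positions every 15 steps
(1.5 ms) and chains consecutive readouts into displacements — increments
over disjoint intervals are independent, so chaining adds data without
correlating displacements (1332 per particle at the 2 s default).

Spherical regions implement spatially varying dynamics: impermeable
(reflecting from both sides; aggregation-like), interaction (D switches to
D_inside while inside; the step's D is that of its start point, first-order
accurate at 0.1 ms), and species (particles initialized inside form a
confined species at D_inside; others ignore the region).

## The recursive correction (SbRD)

For each pixel (or pooled region), the measured displacement start points
are re-embedded in 3D by drawing z uniform over the local chord
[-h(x,y)/2, +h(x,y)/2]; starts that localization error places marginally
outside the outline are projected 1 nm inside. From these starts a 15-step
(1.5 ms) simulation at a candidate D is run with reflecting walls (including
the septum for daughters of a division), the endpoints are projected, and
the simulated apparent coefficient is computed with the same estimator
family as the measurement: the plain Rayleigh MLE for simulation-derived
targets, or the truncated (r ≤ r_max) Rayleigh MLE when the target came from
the truncated in-vivo fit — matching estimator families on both sides of the
recursion removes a systematic offset at high D. The candidate minimizing
the squared difference to the measured value is the corrected coefficient.

Within one repeat the z-assignment and all Gaussian step draws are held
fixed (common random numbers), which makes the simulated output a
deterministic, monotone-increasing function of the candidate; the minimizer
of the squared difference is then the root of (simulated − measured), found
by bracket expansion from the measured value plus Brent's method
(tolerance 1e-3 μm²/s, bounds [0.001, 200] μm²/s), falling back to bounded
scalar minimization if no sign change exists. The whole search is repeated
10 times with fresh z-assignments and noise, and the minimizing candidates
are averaged; under this scheme averaging candidates and averaging output
maps coincide. Corrected minus apparent values form the difference map.

## Synthetic data

The generator emulates the acquisition: uniform-in-3D starts inside each
cell, one lag of simulated motion, projected start/end emitted as peaks in
consecutive frame pairs (round-robin, about one photoconverted molecule per
cell per pulse pair), uniform Poisson background localizations over the
field of view, and optional Gaussian localization jitter (default 0 for
oracle tests; 20 nm is a realistic option). Dividing-pair scenes build two
abutting daughters sharing a reflecting septum, with the distal (old) poles
simulating at D·(1−deficit). What the generator does not emulate:
fluorophore photophysics (blinking, bleaching), localization-precision
heterogeneity, drift residuals, and non-rod morphologies — passing tests
demonstrate correctness of the analysis chain under the model's assumptions,
not robustness to those effects.

## Benchmarks and problem sizes

The bundled studies (`sbrd.benchmarks`) use: 3–4×10⁵ displacements for the
apparent-bias benchmarks (300 particles, 2 s); ~6.5×10⁴ displacements per
sweep point for correction recovery (100 particles, 1 s, 10 repeats);
20 cells at 4000 displacements each for the pipeline-level pole/center
study; 50 dividing pairs (100 daughters) at 3000 displacements per daughter
for the pole-asymmetry power check. These sizes put sampling error well
below the effect sizes being asserted while keeping each study in the
minutes range on one CPU.

## Numerical choices and known limitations

- Pixel assignment uses half-open intervals; the grid is anchored at the
  billiard center, so the innermost pixel spans ±50 nm around the centroid.
- The pole/center region boundary is the cap-center abscissa (the region is
  identified using the billiard's radius).
- The correction model assumes homogeneous D within a pixel's simulation:
  genuine heterogeneity is preserved qualitatively, but a slow region whose
  own confinement differs from the assumed capsule confinement is corrected
  by the capsule's factor, which can overshoot; the slow-pole benchmark
  quantifies this (the region stays clearly below bulk, ~20% above its true
  value at a D/2 contrast in a 0.3 μm sphere at bulk D = 20).
- Pole-region apparent ratios depend on the pooling convention: pooled
  displacement fits weight by thickness and read ~0.93 at D = 1 in the
  reference cell; an unweighted mean over pole-pixel fits reads ~0.91.
- Seeded runs are bit-reproducible; corrected values at 10 repeats vary by
  well under the assertion tolerances across seeds.
- The septum is modeled as an infinite reflecting plane through the
  cap-circle intersection chord; beyond the chord the plane exits the cell
  body, so the approximation only affects a measure-zero sliver.
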