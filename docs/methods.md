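# Methods

This note documents the models, conventions, numerical choices and known
limitations of `dermapol`.  Empirical statements below are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## Polarization algebra and conventions

Stokes vectors are `(I, Q, U, V)`, right-handed, with `V > 0` meaning
right-circular.  One sign convention must be fixed where textbooks differ;
ours is anchored by the quarter-wave linear retarder at 0°, which maps
`(1,0,0,1) → (1,0,−1,0)` (so `m34 = −1`, `m43 = +1` at axis 0°).  Frame
rotation by φ acts on `(Q, U)` with angle 2φ; a sample rotated by φ has
matrix `R(−φ)·M·R(φ)`.  The MMT parameters are

* `A = 2bt/(b²+t²)` with `b = (m22+m33)/2`, `t = √((m22−m33)²+(m23+m32)²)/2`,
  clamped conventionally to 0 when `b = t = 0` (isotropic pixel);
* `α = atan2(m23+m32, m22−m33)` wrapped into `(−90°, 90°]`, NaN when both
  arguments vanish (no defined orientation); the fibre orientation is
  `x = α/4`, defined modulo 45°.

For a pure linear retarder (retardance δ, axis θ) these reduce to the
closed forms `b = (1+cos δ)/2`, `t = (1−cos δ)/2`, `α = 4θ`; the unit and
acceptance tests verify the implementation against those forms to 1e−9,
and verify rotation invariance of `A` / 4φ-equivariance of `α` on random
physical matrices.

## Single scattering

**Spheres** use the Lorenz–Mie series: downward recurrence for the
logarithmic derivative at `m·x` (seeded ≥15 orders above the Wiscombe
truncation `x + 4.05·x^{1/3} + 2`), upward Riccati–Bessel recurrences at
`x` via scipy's spherical Bessel routines.  The test oracle is a second,
independently coded series that evaluates the textbook coefficient ratios
directly (upward at both arguments); the two agree to 1e−8 in `Qext` at
`x = 10`, and the small-particle limit matches the Rayleigh closed form
within 1%.

**Cylinders** use the infinite-circular-cylinder solution at oblique
incidence: for tilt ζ between the incident direction and the cylinder
axis, with `ξ = x sin ζ` and `η = x √(m² − cos²ζ)`, the series
coefficients for the two incident polarization cases (parallel /
perpendicular to the incidence-axis plane) are combined into the 2×2
amplitude matrix `[[T1, T4], [T3, T2]]` on the scattering cone azimuth Θ
(Θ = 0 forward).  Correctness is checked by three independent identities:
cross-polarized amplitudes vanish at normal incidence; the optical theorem
(extinction from the forward amplitude equals the series sum, 1e−6
relative); and energy closure (quadrature of |T|² over the cone equals the
series `Qsca`, 1e−6 relative).  Jones→Mueller conversion uses
`M = A (J ⊗ J*) A⁻¹` in the (parallel, perpendicular) basis.

Size parameters are computed with the medium wavelength (λ/1.33) and
relative index 1.4/1.33 ≈ 1.0526, since the scatterers are embedded in
the interstitial medium.  Populations are parameterized by their share of
the total scattering coefficient, matching how the damage stages are
specified as sphere:cylinder ratios against fixed μs; number densities
never enter.

**Sampling tables.**  The transport kernel consumes precomputed tables:
1800 scattering angles for the sphere phase function and Mueller ratios;
a 180 (ζ) × 720 (Θ) grid of m11-normalized cylinder Mueller matrices with
per-ζ azimuth CDFs.  Tables are deterministic for a configuration and
cached in memory.  Θ is sampled by discrete inversion of the tabulated CDF
plus a uniform jitter within the cell; matrix values use the nearest grid
cell (0.5° tilt, 0.5° azimuth resolution).

## Monte Carlo transport

Photons start at the top surface already refracted to the internal 15°
direction (specular entry reflection is discarded; the oblique geometry
exists to remove it from the detected light).  Free paths are exponential
with mean 1/μs; the event type is sphere with probability
μs_sphere/μs_total.  Per cylinder event the fibre axis is drawn from a
wrapped normal in the sample plane (mean axis, spread σ); the outgoing
direction preserves the axial component exactly (cone constraint), and
degenerate propagation along the axis is resampled.  The interstitial
birefringence applies, per straight segment, a linear retarder with
retardance `2π·Δn·sin²ψ·ℓ/λ` (ψ = angle between flight direction and the
in-plane optic axis, which defaults to the mean fibre axis) about the
optic-axis projection perpendicular to the flight direction.  At the top
interface, unpolarized Fresnel reflection (including total internal
reflection) is applied probabilistically and reflected photons continue;
photons crossing the bottom face are counted as transmitted and dropped.
There is no absorption, so weights need no roulette; every launched photon
ends in exactly one of four bins (detected, top-rejected, bottom-exit,
terminated at the event cap of 20 000), and the budget identity is exact
by construction.

**Detection convention.**  Detected Stokes vectors are re-referenced to
the laboratory x-axis and expressed in the lab-fixed convention — the one
in which a specular-like return is the identity matrix, as assumed when a
DRR instrument is calibrated on air.  In this convention an isotropic
medium gives `m22 = +m33 > 0`, so the isotropy null drives `A → 0`
through `t → 0` over a stable `b`.  The default aperture aggregates the
full backscattering hemisphere; a finite acceptance cone (e.g. 10°) is
configurable, but at desk-scale photon counts it discards ~98% of the
backscattered light and leaves stage differences statistically
unresolved, so the hemisphere aggregate is the package's default scalar.

**Estimators.**  Two mathematically equivalent estimators are provided.
The default (`stokes`) traces four sub-ensembles with H, V, +45° and
right-circular inputs — `n_photons` each, the four illuminations of a real
polarimetric measurement — and assembles the matrix columns from their
mean detected Stokes vectors.  Each photon carries a unit-intensity Stokes
vector; scattering azimuths are importance-sampled from the polarized
single-scattering intensity (rejection over the unpolarized tables), so
every detected contribution is bounded (|Q|,|U|,|V| ≤ I = 1).  The
cylinder ensemble's polarization-dependent total gain (its diattenuation)
is carried as a scalar weight using the per-ζ phase-averaged first-row
elements.  The four ensembles share a common random seed, which correlates
the paths and reduces the noise of column differences such as H−V.  The
alternative (`matrix`) estimator accumulates a per-photon cumulative 4×4
path matrix, yielding the whole Mueller matrix from a single ensemble;
its per-photon contributions are heavy-tailed (products of m11-normalized
event matrices are unbounded), which is why it is not the default for
small-signal scalars, but for strongly oriented media it gives the
tighter batch standard error and is used by the stage sweeps.  The two
estimators are cross-checked against each other in the test suite.

When the medium is statistically invariant under the mirror `y → −y`
(sphere-only, or fibre/optic axes at 0° mod 90°, which covers the standard
stage configurations), the aggregate is symmetrized as `(M + D·M·D)/2`
with `D = diag(1,1,−1,−1)` — an exact, unbiased cancellation of noise in
the elements that vanish by that symmetry.  The anisotropy contrast
`m22 − m33` is unaffected, so the isotropy null remains a genuine test.

Uncertainties are batch-means standard errors over 10 batches.
Reproducibility is bit-exact for a given configuration and seed
(single-threaded kernel, one legacy-RNG stream).

**Problem sizes.**  The isotropy null uses 1e6 photons per input state;
the stage sweeps use 2e5 photons per configuration with matched per-stage
seeds across the two sweeps, which makes the no-sunscreen vs sunscreen
drop comparison a paired one.  These sizes resolve the stage gaps at
several standard errors while keeping a full acceptance run at a couple
of minutes on one CPU.

## Dual-rotating-retarder polarimeter

Unpolarized unit-intensity light passes a horizontal polarizer, a rotating
quarter-wave retarder, the sample, a second rotating quarter-wave
retarder, and a horizontal analyzer.  The two retarders advance at a 5:1
rate ratio over 30 frames; the slow one steps 6°/frame (180° total).  The
rate ratio's arm assignment is configurable and reconstruction is
indifferent to it because the 30×16 design matrix (rows = analyzer-row ⊗
generator-state outer products) is built from the actual schedule; it has
rank 16 with condition number ≈ 13 for either assignment.  Reconstruction
is pseudo-inverse least squares — exact for any full-rank schedule, with
noiseless round trips at ~1e−12 — rather than Fourier harmonic analysis;
half-wave retardances collapse the rank to 9 and raise a conditioning
error naming the condition number.  With zero-mean Gaussian intensity
noise of 0.1% of the mean signal, identity-sample reconstruction errors
are of order 0.01 — the scale of a well-calibrated hardware system — and
grow linearly with the noise level in the small-noise regime.

## Orientation statistics

The FDH of α uses 400 equal bins spanning (−90°, 90°] (0.45° width) and
is area-normalized to 1 exactly; NaN (isotropic) pixels are excluded and
counted.  Because α lives on a 180°-period circle and measured peak
positions depend on how the sample happened to be oriented, the spread
statistic recentres the sample at the circular mean of 2α before taking
the ordinary linear standard deviation.  This makes the statistic
invariant under global rotations of the orientation field (checked to
0.1°), equal to 180°/√12 ≈ 51.96° in the uniform-disorder limit, and
within 5% of the generating σ for wrapped normals up to σ ≈ 40°.  Beyond
that, wrapping compresses the measured spread (a wrapped normal with
σ = 51° measures ≈ 45°) — a documented bias, relevant because heavily
damaged skin is close to the uniform limit.

Stage reports flag "damaged" when, relative to the first timepoint, the
mean `A` drops by ≥ 0.03 **and** the α spread rises by ≥ 8° — thresholds
chosen below the protected-group effect sizes (A drop 0.03–0.04, spread
rise ≈ 10°) so that even sunscreen-protected damage is called — and
"recovered" when the final timepoint returns within those same tolerances
of baseline.  Both thresholds are configurable.

## Synthetic skin images

The generator emulates the *statistical* structure of staged measurements,
not their photorealism.  Per pixel, an orientation is drawn from a
spatially correlated wrapped-normal field and an anisotropy target from a
correlated field around the stage mean; the pixel matrix is a linear
retarder at that orientation whose retardance is solved from the target
`A` (inverting `A = 2r/(1+r²)` on the `r ≤ 1` branch), composed with an
isotropic partial depolarizer that sets realistic element amplitudes
(m22 ≈ 0.15–0.5) without touching `A` or `α`.  Element-wise Gaussian
noise (σ = 0.005 by default) emulates measurement noise.  Preset spreads
are specified as the *measured* statistic; the generator inverts the
wrapping bias numerically (bisection on the wrapped-normal variance
integral), so the damaged preset reproduces a measured spread near 51°
rather than the 45° a naive σ = 51° field would give.  The spatial
correlation length (8 px) is cosmetic texture, not tissue physics.
Trajectories share one texture across timepoints (the same animal imaged
repeatedly) and interpolate stage parameters linearly through damage and
repair phases.

What passing tests on these fixtures shows: that the measurement chain
(DRR forward/inverse, MMT extraction, statistics) recovers the generating
stage parameters through realistic noise.  What it cannot show: anything
about real-tissue effects absent from the generator — depolarization
heterogeneity, specular residue, spatially varying birefringence, CCD
artifacts.

## Numerical defaults

Analytic identity tolerance 1e−9; angular tolerance 1e−6°; Mie truncation
by the Wiscombe criterion; cylinder series truncated at
`ξ + 4.05·ξ^{1/3} + 8` orders; lookup grids 1800 (sphere θ) and 180×720
(cylinder ζ×Θ); DRR conditioning limit 1e8 on the design-matrix condition
number; MC event cap 20 000 (terminations are counted in the budget, and
at the modeled optical thickness of 10 they are absent in practice).

## Limitations

* The slab is homogeneous; real skin is layered (epidermis/dermis) and
  absorbing.  The bottom boundary is absorbing (no sample-holder
  reflection).
* Interface Fresnel factors are polarization-averaged; the small
  polarization bias of refraction near the acceptance cone is neglected,
  and total-internal-reflection phase shifts are ignored.
* Cylinder axes are confined to the sample plane, consistent with an
  in-plane orientation parameter; out-of-plane fibre dip is not modeled.
* The simulated `A` is an aggregate over the backscattering hemisphere;
  spatially resolved simulation output is not implemented.
* Monodisperse scatterers only; no size distributions or coated particles.
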