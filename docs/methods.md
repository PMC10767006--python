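# Methods

This note records the models, assumptions, parameter choices and numerical
decisions behind `arterymech`, in the spirit of a methods section a
maintainer can audit.

## Thin-wall extension–inflation analysis

**Model.** The artery is a thin-walled incompressible cylinder. At each
pressure step the deformed inner diameter follows from conservation of wall
volume between the traced unloaded ring (outer/inner diameters Dₒ, Dᵢ) and
the loaded state at axial stretch λz:
dᵢ = √(dₒ² − (Dₒ² − Dᵢ²)/λz). Mean biaxial Cauchy stresses are
σ_θ = P·rᵢ/h and σ_z = (f + P·π·rᵢ²)/(π·h·(2rᵢ + h)). The circumferential
form is not an approximation for thick walls: integrating radial equilibrium
shows that the through-wall *mean* σ_θ equals P·rᵢ/h for any incompressible
cylinder, which the test suite verifies against a numerically integrated
neo-Hookean thick-wall solution.

**Assumptions.** The traced unloaded ring is the reference configuration;
residual stress (opening angle) is ignored. Passive behavior only — no
smooth-muscle tone.

**Conventions and units.** Pressures are stored in mmHg and converted with
1 mmHg = 0.1333224 kPa only where stresses are formed; lengths in mm, forces
in mN, stresses in kPa, moduli in MPa. With mm/mN/kPa the stress formulas
are dimensionally closed (1 kPa·mm² = 1 mN).

**Circumferential stretch.** λ_θ is the mid-wall circumference ratio
(dₒ + dᵢ)/(Dₒ + Dᵢ) by default — the natural partner of *mean* wall
stresses. An inner-wall convention (dᵢ/Dᵢ) is available via the
`convention` argument. Reported values depend slightly on this choice,
which is why it is exposed rather than hidden.

**In vivo axial stretch.** The in vivo stretch is the tested λz whose axial
force varies least during the pressure sweep. The plateau metric is the
force range (max − min) — the strictest simple choice; standard deviation is
available as an option. The estimate is declared `within_threshold` when
the variation is ≤ 0.05 mN (50 μN). Optional parabolic interpolation
through the three lowest (λz, variation) points refines the estimate
between tested stretches; it is off by default so the estimate is always a
tested stretch. Note that with the default simulated instrument noise
(0.05 mN SD per force sample), the range of 13 noisy samples is ~0.17 mN
even at a perfect plateau, so the strict threshold is only attainable on
low-noise (or noise-free) data; the λz estimate itself is unaffected.

**State at MAP.** All state fields are interpolated linearly in pressure
between the two bracketing protocol steps (10 mmHg apart). Linearly
interpolated states satisfy the incompressibility identity only to within
the interpolation error; the identity is enforced exactly on processed
(non-interpolated) states.

**Tangent modulus.** dσ_θ/dλ_θ at the target pressure comes from a local
quadratic least-squares fit through the five (λ_θ, σ_θ) samples nearest in
pressure, differentiated at λ_θ(P). This is robust to the 10 mmHg
discretization and exact for quadratic stress–stretch data; a central
finite difference is available as an option. Degenerate stretch spacing
raises rather than returning a meaningless slope.

## Membrane constitutive simulator

**Model.** Incompressible plane-stress membrane with a neo-Hookean ground
matrix and exponential fiber families (stiffness c1 in kPa, dimensionless
exponent c2, angle φ from the axial direction), the standard description of
rodent arterial tissue. Stresses are σ_θ = λ_θ·∂W/∂λ_θ, σ_z = λ_z·∂W/∂λ_z
of the reduced energy; fibers carry load in compression as well (no tension
cutoff), which keeps the response smooth through λ_θ < 1 — the regime an
axially stretched tube actually occupies at zero pressure.

**Kinematics.** Mid-wall radius r = λ_θ·R_mid with membrane thickness
update h = H/(λ_θλ_z); emitted outer diameter dₒ = 2(rᵢ + h). The annular
wall area implied by this kinematics equals the area the incompressibility
relation assigns, so the analysis side recovers the simulator's mid-wall
stretch, stresses, pressures and forces exactly on noise-free data — the
round-trip is an identity, not an approximation.

**Equilibrium solve.** σ_θ(λ_θ)·h/rᵢ = P is solved by bisection. The
bracket is [0.25, 4.0] clipped from below so that rᵢ > 0; the lower part
below 1 is required because at P = 0 an axially stretched tube contracts
circumferentially. Axial stretches at which no pressurized equilibrium
with a positive lumen exists are treated as infeasible (NaN) during grid
searches and as errors during direct simulation.

**Presets.** The defining experimental property of the in vivo stretch is
that axial force is pressure-invariant there to within ~50 μN. Generic
parameter choices in this constitutive family miss that by an order of
magnitude, so the two presets were calibrated once, offline: force flatness
is *linear* in the stiffnesses {c, c1k} at fixed angles/exponents/λz
(because f = (2πR_mid·H/λz)·(σ_z − (rᵢ/2r)·σ_θ) identically), so
nonnegative least squares over a dictionary of candidate fiber families
yields presets whose axial-force range over the sweep is 16 μN (CTL-like,
λz* = 1.75) and 9 μN (HT-like, λz* = 2.00), while the 100 mmHg state lands
at physiological values (σ_θ/σ_z ≈ 85/122 kPa and 137/174 kPa
respectively). The full-precision coefficients in `preset()` are part of
this design; rounding them destroys the invariance. The presets are
illustrative of their groups, not fits to any particular animal; their
tangent moduli (≈0.85 and ≈1.24 MPa) are stiffer than typical group means
because flatness and stress targets took priority over a modulus target in
the calibration.

**Inter-animal variability.** `perturbed_preset` draws a common log-normal
multiplier on all stiffnesses (σ = 0.10) and a log-normal geometric scale
(σ = 0.05). These two transformations — unlike independent per-parameter
jitter — preserve the designed force invariance: scaling geometry leaves
the pressure–stretch relation unchanged, and scaling all stiffnesses
re-maps the sweep to an equivalent pressure range the design window covers.

**Noise.** Additive Gaussian, defaults 5 μm SD on diameter and 0.05 mN SD
on force; all randomness flows from explicit seeds.

## Synthetic fiber images

The generator emulates 425 × 425 μm multiphoton fields on a 512 × 512 grid
(pixel ≈ 0.83 μm) with 1 μm z-spacing. Fibers are single-harmonic
sinusoids: a perpendicular perturbation of amplitude A and wavelength L
about a straight axis, rasterized by splatting the centerline and blurring
with a Gaussian of σ = width/2. Fiber length is an integer number of
periods, so the chord equals the axial extent and the straightness
parameter has the closed quadrature form Ps = L/∫√(1 + (A·k·cos ku)²)du —
the oracle shared with the straightness tests (Ps(A = 0.1L) ≈ 0.915).
Orientations are axial von Mises (doubled-angle construction) or fixed;
depth stacks switch distribution at a prescribed interface depth. Fibers
are placed with margins so the whole centerline fits in frame (bounded
retries); fibers longer than the frame are clipped with truth restricted
to the in-frame portion.

What the generator does **not** emulate: optical point-spread anisotropy,
depth-dependent attenuation, 3-D fiber continuity across slices, fiber
bundling/crimp heterogeneity. A green recovery test therefore establishes
correctness of the estimators under idealized imaging, not robustness to
every property of real SHG stacks.

## Orientation analysis

Mean subtraction, a 2-D raised-cosine taper, |FFT|², and angular binning of
spectral power over an annulus (radii 2 to 0.9 × Nyquist in index units)
with a 90° rotation into fiber space; 2° bins on [−90°, 90°), 0° = image
x-axis = vessel axis, angles measured toward increasing row index. The
taper is a Tukey window with α = 0.25 rather than a full Hann: a full Hann
down-weights most of the field, roughly halving the effective fiber count
and inflating the circular-mean scatter beyond the 3° recovery budget on
seeded von Mises images; a quarter taper keeps the edge-leakage suppression
(rotation equivariance within one 2° bin) at full interior weight. α and
the annulus are exposed.

Stack aggregation averages per-slice histograms bin-wise and renormalizes;
per-slice normalization (each depth row of the depth map sums to 1) was
chosen over per-stack normalization so depth rows are comparable as
distributions. Qc/Qa uses symmetric ±20° windows about the axial and
circumferential directions by default (window widths are reported in
outputs); the ratio of the stack-mean histogram is the default aggregate,
with per-slice ratios available by applying the operation per row.
Near-empty slices that yield no spectral content are skipped and counted,
not fatal.

## Straightness analysis

Preprocessing is a difference of Gaussians (σ = 1 and 8 px) with clipping
and max-normalization — scale-invariant and dependency-light, standing in
for curvelet denoising. Tracing: Otsu binarization, medial axis (the ridge
of the Euclidean distance transform) with its distance values, nucleation
at unvisited ridge pixels in decreasing distance order, bidirectional
extension choosing the neighbor best aligned with the running direction
(U-turns refused), and straight-ahead gap probing up to `max_gap_px`
(default 4 px). The medial-axis call is given a fixed rng because its
tie-breaking is otherwise randomized, which would make tracing
non-deterministic. Traced polylines are smoothed with a 7-point moving
average (endpoints kept, so the chord is exact) before Ps = chord/arc;
fibers shorter than 25 μm are dropped. Defaults are exposed; they are not
claimed to equal any external tracer's internal settings — recovery against
synthetic truth (median Ps within 0.05 of the quadrature oracle for
Ps ∈ [0.75, 1]) is the contract.

Per-slice medians are computed on raw per-fiber values, not on binned
histograms; stack summaries are the mean ± SD of per-slice medians.

## Statistics

Mean ± SEM for mechanics, mean ± SD for imaging (convention recorded on
every summary); sample (n−1) SD throughout; n = 1 dispersion is reported as
a flagged zero so tables always render. One-way ANOVA (F = MSB/MSW) with
classical equal-variance pairwise t tests and Bonferroni adjustment
min(1, m·p); Welch tests are an option. The test suite checks F/p against
a brute-force sums-of-squares oracle and the type-I error of the whole
recipe on permuted null groups.

## Known limitations

- The mechanics analysis and the simulator share the mid-wall convention;
  analyses of real data with a different λ_θ convention will differ by a
  known kinematic factor (use the `convention` option).
- The 50 μN plateau flag is a property of noise level as much as of the
  tissue; see the in vivo stretch section.
- Fiber tracing merges crossing fibers or splits dense bundles in heavily
  overlapping fields; count-accuracy guarantees hold for well-separated
  fibers only.
- 2-D slice-wise analysis throughout; no 3-D fiber reconstruction.
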