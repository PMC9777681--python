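# Methods

This note records the models implemented by `gelmech`, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter.

## Ring tensile kinematics and stress

The ring test stretches an oval specimen between two pins of diameter
*d*.  As the top pin travels a distance Δs, both straight segments of
the oval lengthen, so the inside circumference grows as

    C_i = C_0 + 2 Δs,   D_i = C_i / π,

with the initial inside circumference C₀ taken from specimen geometry
(default 60 mm; pin diameter 6 mm, width w = 5 mm, thickness 5 mm —
all configurable, since specimen drawings rather than printed numbers
define them).  Treating the ring wall as a thin pressurised shell,
Laplace's law gives the circumferential wall stress

    σ_r = F / (w · D_i).

Width and thickness are held constant during the test: measured
dimension changes in gels of this stiffness are below 0.5 mm and are
ignored.  The engineering strain is the relative circumference change
ε_r = (C_i − C_0)/C_0, consistent with both the true-stress conversion
σ_true = σ_r(1 + ε_r), ε_true = ln(1 + ε_r) and with observed gel
failure strains of order 0.1.  (A stretch-ratio definition C_i/C_0
would be incompatible with the (1 + ε) conversion and with that
magnitude.)

Young's modulus is the origin-anchored least-squares slope over the
first `linear_fraction` (default 0.4) of the pre-failure true-strain
range.  The fraction is configurable because where the linear region
ends depends on the yield strain; for materials whose yield strain is a
small fraction of the failure strain a smaller value should be passed.
The elastic/plastic split is pointwise: ε_elastic = σ_true/E (clipped
at the total strain), ε_plastic the remainder; the yield index is the
first sample whose stress deviates from the elastic line by more than
2% relative (configurable — a conventional small-offset criterion).

Failure is the first local stress maximum followed by a drop exceeding
50% of the peak (configurable).  The large threshold distinguishes
complete specimen separation from the gradual fracture plateaus that
gels show under compression.  A curve with no qualifying drop is
reported as *censored* with its global maximum, so analyses of records
that end at failure still return the failure point.

## Compression

Engineering measures only: σ_c = F/A, ε_c = ΔL/L with the cylinder's
contact area and initial height (defaults 25.4 mm diameter, 20 mm
height).  No hydraulic-pressure correction is attempted; pore-water
effects are exactly what makes compression unreliable for these gels
and motivates the ring test.

## Johnson–Cook model

Flow stress σ = (A + B εₚⁿ)(1 + C ln(ε̇ₚ/ε̇₀)) with 0ⁿ := 0, so the
stress at yield onset is exactly A times the rate bracket.  The thermal
softening bracket is disabled (factor 1): frictional heating during a
gel test at room temperature is negligible.  For the same reason the
trailing temperature factor of the fracture-strain expression is fixed
at 1; the constant d₅ is stored for config compatibility but inert.
For rates far below the reference rate the rate bracket would go
non-positive; it is floored at 1% of its unit value with a warning,
since such rates are outside the regime where the model is used.

Fracture strain ε_f = [d₁ + d₂ e^(−d₃ η)][1 + d₄ ln(ε̇ₚ/ε̇₀)] with
triaxiality η = σ_m/σ̄, fixed at 1/3 (uniaxial tension) inside the
material-point driver.  Damage D accumulates as the integral of
1/ε_f dεₚ; failure at D = 1.

### Parameter estimation

`fit_hardening` estimates (A, B, n) by nonlinear least squares, but the
exponent is handled by variable projection: for fixed n the optimal
(A, B) are a linear solve, and the profiled residual is minimised over
a log-spaced n grid refined by bounded scalar minimisation, followed by
a joint Levenberg polish.  The profiled path matters because the gels
modelled here have n as small as ~10⁻³, where σ ≈ (A + B) + B·n·ln εₚ
and the A/B split is identified only through the tiny curvature in
ln εₚ — a single joint descent from a generic start reliably stalls in
that valley, while the profiled solve recovers all three parameters to
machine precision on noiseless data.  The 10% test tolerance on n (vs
1% on A and B) acknowledges that with any noise the exponent is the
ill-conditioned direction.

`fit_damage` estimates (d₁…d₄) from (fracture strain, triaxiality,
rate) observations, with explicit identifiability guards: d₃ requires
at least two distinct triaxialities and d₄ two distinct rates,
otherwise the constant must be frozen via config rather than silently
fitted.

### Material-point tensile driver

A strain-driven explicit integrator stands in for 3-D explicit-dynamics
finite elements: the ring-tensile strain field is essentially
homogeneous until failure, so a single material point captures the
constitutive response at a tiny fraction of the cost.  Each step
applies an elastic predictor σ = E(ε − εₚ); when the trial exceeds the
current yield surface, the new plastic strain solves
E(ε − εₚ) = (A + B εₚⁿ)(rate bracket) by bracketed root finding
(Brent), which is robust to the infinite slope of εₚⁿ at zero for
n < 1.  Default strain step 10⁻³ — unconditionally adequate for
monotonic loading at this scale.  Damage uses trapezoidal quadrature of
1/ε_f over the plastic-strain path so it matches an independent
trapezoid integral to ~10⁻¹²; the run stops at the first sample with
D ≥ 1, so the failure point overshoots the exact fracture strain by at
most one step.

## LAOS analysis

The strain drive is γ = γ₀ sin ωt.  Harmonic moduli come from discrete
Fourier projection over an integer number of cycles after discarding
the first (transient) cycle: for uniformly sampled band-limited signals
over whole periods the rectangle rule is exact (and coincides with the
trapezoidal rule), so recovery of configured coefficients is at machine
precision.  Projections beyond the per-cycle Nyquist limit and
non-integer cycle counts are rejected.

Lissajous–Bowditch loops take the final cycle, closed by repeating its
first sample; the strain-rate axis is analytic (γ₀ω cos ωt) rather
than numerically differentiated, avoiding noise amplification.  For a
linear material the elastic loop is an ellipse of area πγ₀²G″, which
the shoelace formula reproduces to O((2π/N)²) — 0.01% at 256
samples/cycle.

Nonlinearity measures: I₃/I₁ (third- to first-harmonic stress
amplitude ratio) and the strain-stiffening ratio
S = (G′_L − G′_M)/G′_L with G′_M = Σ k G′_k (tangent modulus at zero
strain) and G′_L = Σ G′_k sin(kπ/2) (secant modulus at maximum
strain).  Under this standard convention a *negative* sin-3ωt elastic
coefficient produces intracycle stiffening (S > 0); the generator's
third-harmonic coefficients map sign-for-sign onto the recovered
G′₃/G″₃, so stiffening test signals are configured with e₃ < 0.

The LVR critical strain is the first sweep amplitude at which G′ falls
more than 10% (configurable) below the median of the first three
levels; a sweep with no such drop reports the region as unbounded
within the sweep rather than erroring.  Default sweep conditions mirror
the study design: amplitudes from 1% to 100%, frequencies 1 and 10 Hz.

## Digital image correlation

Subset matching by zero-normalized cross correlation (robust to
uniform lighting changes): each grid point's odd square subset (default
21 px, spacing 10 px) is searched over integer offsets within a
configurable radius, then refined by a full 2-D paraboloid fit of the
3×3 correlation neighbourhood (clipped to ±0.5 px; skipped when the
integer peak is numerically perfect, where refinement could only add
noise).  Points whose search window leaves the image or whose peak
correlation falls below the threshold are masked.  Strains come from
local least-squares plane fits of u and v over 3×3 grid neighbourhoods.
The strain-concentration index max(εxx)/median(εxx) summarises
localisation: ~1 for homogeneous elongation, large at an incipient
crack.

This is deliberately a zeroth-order matcher — no iterative subset
shape-function optimisation.  On the translation-dominated, ≤1–2%
strain fields of gel ring tests it tracks synthetic ground truth to
better than 0.05 px RMS; accuracy degrades for large rotations or
strong intra-subset strain gradients, which full DIC packages handle
and this module does not claim to.

## Synthetic data generator

The generator is declared to be exactly the elastic + Johnson–Cook
forward model the pipeline fits — this is stated openly: recovery and
closure tests demonstrate the *pipeline's* correctness (inversion,
calibration, numerics), not the physical fidelity of the constitutive
law to real gels, for which no raw instrument data are available.

* **Ring tensile**: true-strain history from the constant crosshead
  speed (default 1 mm/s, 50 samples/s mirroring 50 fps video),
  integrated through the material point; force back out through the
  ring geometry (F = σ_true·w·C₀/π, which makes the noiseless
  round-trip exact by construction).  Gaussian force noise is scaled to
  the peak force.
* **Round-trip calibration**: targets are an engineering failure
  stress/strain pair.  The failure true strain is split 40% plastic /
  60% elastic (fixing E), yield is placed at 60% of the failure true
  stress, n = 0.5, and B follows from passing exactly through the
  target; damage is a constant fracture strain equal to the plastic
  part.  The split fractions are design choices, not fits: the
  tabulated Young's moduli for the xanthan blends are incompatible with
  their measured failure points under elastic–plastic kinematics
  (σ_true at failure exceeds E·ε_true), so a self-consistent modulus
  must be derived from the target itself.
* **Compression**: two-term convex law σ = k₁ε + k₂εᵖ (p = 2) with the
  linear term carrying half the configured peak stress, a 60% stress
  drop at the configured failure strain, and elongation to 80% strain —
  a qualitative match to the strain-hardening-then-broad-failure shape
  of gel compression curves, kept two-parameter simple.
* **LAOS**: σ = γ₀[G′ sin ωt + G″ cos ωt + e₃ sin 3ωt + v₃ cos 3ωt]
  plus optional Gaussian noise.  No intercycle transient is modelled,
  so the analyzer's transient-discard is exercised only structurally.
* **Speckle images**: dark Gaussian blobs (σ = 3 px, 0.01 /px²) on a
  light background, 8-bit; the deformed image is the reference warped
  by the affine field with cubic-spline interpolation (an exactly
  identity deformation skips the warp so the pair is bitwise equal).
  Deformations that would carry speckle content out of frame are
  rejected.

All generators are bitwise reproducible from their seed.

What the generator does **not** emulate: water exudation and pore
pressure, specimen-to-specimen variability, instrument compliance and
inertia, viscoelastic stress relaxation in the tensile records,
intercycle transients in LAOS, and camera optics (lens distortion,
motion blur, perspective).  Passing closure tests therefore validate
the analysis chain, not these physical effects.

## Problem sizes

Defaults used by the test suite and the acceptance script: tensile
records of ~120–200 samples (50 Hz to failure), hardening fits on 200
samples, LAOS waveforms of 4 cycles × 256 samples, speckle images of
256×256 px with ~480 grid points.  These sizes were chosen so every
result is converged well past its test tolerance while the whole suite
runs in seconds.

## Known limitations

* The damage constants d₁–d₄ for the real gels are not published;
  damage-model checks rest on synthetic recovery.
* The ring analysis assumes monotonic loading; unloading/reloading
  records violate the non-decreasing-strain contract of the curve
  container by design.
* `waveform_from_arrays` infers the fundamental from the dominant FFT
  bin and requires uniform sampling over whole cycles; arbitrary
  rheometer exports may need resampling first.
* The DIC matcher is zeroth-order (see above) and single-pair; video
  sequences are handled by looping calls.
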