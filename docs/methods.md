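# Methods

This note records the models implemented in `collitrans`, their assumptions,
the defaults that matter, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

Unit conventions throughout the package: lengths in mm, coefficients
(µ_a, µ_s, µ_t) in 1/mm, wavelengths in nm, sphere diameters in µm, angles in
radians. All refractive indices may be constants, callables of wavelength, or
two-column dispersion tables; the package ships no material database —
dispersion data are user-supplied.

## Multireflection model (`multireflection`)

A plane-parallel slab between two interfaces of Fresnel transmission
T_I = 1 − ((n₁−n₂)/(n₁+n₂))² transmits, over all internal reflection orders,

    T_tot = T_I² T_M / (1 − T_M²(1−T_I)²),
    R_tot = (1−T_I) + (1−T_I) T_I² T_M² / (1 − T_M²(1−T_I)²),

the closed forms of the geometric series over orders; T_M = e^(−µ_t d) is
the single-pass internal transmission. A cuvette wall (surround | glass |
medium) is itself a lossless slab, giving the composite wall transmission
T_G = T_G1·T_G2 / (1 − (1−T_G1)(1−T_G2)) that replaces T_I.

Assumptions: normal incidence (perpendicular-incidence Fresnel formulas),
incoherent addition (no etalon fringes), non-absorbing non-scattering walls
(wall reflectance is exactly 1 − T_G).

**Inversion.** Solving T_tot for T_M is a quadratic; the physical root is
the positive branch (the other root is non-positive for every feasible
input — asserted on a grid in the tests). It is evaluated in the conjugate
form T_M = 2·T_tot / (T_I² + sqrt(T_I⁴ + 4·T_tot²(1−T_I)²)), which is free
of subtractive cancellation for small T_tot and regular at T_I = 1. Measured
transmissions up to 1e-6 relative above the transparent-medium ceiling are
clipped to T_M = 1 (values rounded to a few digits would otherwise be
rejected); anything further above raises an infeasible-input error.

**Reference convention.** The reference measurement is the same cuvette
filled with a non-absorbing, non-scattering medium of the *same* refractive
index as the sample medium; a different reference index is accepted as an
option. Because the reference medium is transparent and its index known, the
pipeline recovers absolute sample transmission from the measured ratio by
scaling with the model transmission of the reference cuvette.

**Neglect-error study.** Evaluating forward-modelled cuvette transmissions
with plain −ln(I/I₀)/d overestimates weak absorption; the relative error
decreases monotonically in µ_a, converges to 2r²/(1−r²) (r = 1−T_G) as
µ_a → 0 — derived by expanding the ratio of the series forms to first order
in µ_a·d — and decays like −ln(1−r²)/(µ_a d) at strong absorption. The
closed-form limit doubles as an independent oracle for the numeric curve.

## Scattering models (`mie`, `scattering`)

**Mie series.** Partial-wave coefficients a_n, b_n are computed with the
classical stable scheme: logarithmic derivative D_n(mx) by downward
recurrence (started 16 orders above max(n_max, |mx|)), Riccati–Bessel
ψ_n(x), χ_n(x) by upward recurrence, truncation at
n_max = ⌈x + 4.05 x^(1/3) + 2⌉. Efficiencies, the asymmetry parameter g
(adjacent-order cross products), and amplitudes S₁/S₂ (π_n/τ_n recurrence,
vectorised over angle) follow the standard sums. Complex m (absorbing
spheres) is supported; for real m the optical theorem Q_ext = Q_sca holds to
1e-10 and is tested. The size parameter is capped at 2·10⁴, beyond which the
double-precision recurrences are not trusted; the cap raises an explicit
error. The tests cross-check against an independent route (direct
`scipy.special.riccati_jn/riccati_yn` evaluation of the same coefficients)
and against the Rayleigh closed form (8/3)x⁴|(m²−1)/(m²+2)|².

At size parameters of several hundred, nearby morphology-dependent
resonances make individual coefficients sensitive at the ~1e-4 level to the
evaluation route; efficiencies agree with the independent route to ~1e-4
relative there, and to 1e-10 at moderate x. This is adequate for every use
in this package (phase-function shapes and spectra, not resonance
metrology).

**Phase-function tables.** The unpolarised phase function is
p(θ) ∝ |S₁|² + |S₂|², normalised so 2π∫p sinθ dθ = 1 by the trapezoid rule.
The default θ grid is geometric toward θ = 0 (resolving the diffraction
lobe, whose first zero sits near the Airy angle 1.22π/x) and is refined
adaptively — grid density doubles until the forward-lobe integral is stable
to 1e-4 relative; failure to converge raises an error rather than returning
an unresolved peak. Tabulated sampling inverts the trapezoid CDF with linear
within-bin interpolation in θ.

**Henyey–Greenstein.** p(θ) = (1−g²)/(4π(1+g²−2g cosθ)^{3/2}) with the
exact inverse-CDF sampler, and the closed-form cone fraction
F(θ_c) = ((1−g²)/2g)·(1/(1−g) − 1/sqrt(1+g²−2g cosθ_c)); below |g| = 1e-6
the isotropic limit (1−cosθ_c)/2 is substituted to avoid cancellation.

**Suspensions.** µ_s(λ) = Σ_i N_i C_sca,i over Gauss–Hermite nodes
(default 11) of the Gaussian diameter distribution, with the volume fraction
apportioned to nodes by the Gaussian weight and number density
N_i = c·w_i/((4/3)πa_i³); the monodisperse case collapses to one node. The
size parameter uses the in-medium wavelength λ/n_medium. µ_s is exactly
linear in c. Volume fractions above 0.05 warn about dependent scattering
(the independent-scattering assumption, not corrected here). Mixture phase
functions weight each node's |S₁|²+|S₂|² by number density; the in-medium
wavenumber is common to all nodes and cancels in the normalisation.

The wavelength for single-wavelength phase-function studies defaults to
600 nm with n_water = 1.33 and n_polystyrene = 1.586; both are configurable.

## Monte Carlo transport (`monte_carlo`)

Unpolarised energy packets in a plane-parallel slab: free paths ~ Exp(µ_t);
at each collision the packet deposits weight µ_a/µ_t (implicit capture) and
deflects by a phase-function draw with uniform azimuth (MCML-style direction
spin with the polar special case). Russian roulette below weight 1e-4 with
survival factor 10 — irrelevant in the scattering studies, which run at
µ_a = 0 where all weights stay exactly 1 and the transported weight budget
(transmitted + reflected + residual) closes to machine precision.

**Detection model.** The instrument focuses the transmitted beam onto a
pinhole with a parabolic mirror: exit *angle* maps to focal-plane position
(x = f·θ). A rear-face exit is detected iff its direction lies within the
acceptance half-angle NA_det = (pinhole_det/2)/f and its lateral exit
position lies within the mirror aperture (default 25.4 mm, a one-inch
mirror). The ballistic tally counts zero-scatter packets only. The
illumination is an ideal axial pencil beam: the real illumination NA
(3.29·10⁻⁴) is twenty times smaller than the detection acceptance and is
neglected.

**Boundaries.** `matched` (no reflection or refraction; used for the
forward-scattering studies so the error isolates scattering effects) or a
cuvette: each wall reflects specularly with its normal-incidence composite
reflectance 1 − T_G — exact for the axial packets of absorption
measurements, a sub-milliradian-angle approximation otherwise — including
the entrance wall at launch, and exit directions refract by Snell's law into
the surroundings. With µ_s = 0 this reproduces the multireflection closed
form exactly in expectation; the agreement within statistical uncertainty is
a test and part of the acceptance checks.

**Error study.** For each optical thickness τ = µ_t·d_s, µ_s is evaluated
from the detected transmission as µ̂_s = −ln(T_detected)/d_s (reference
implied ideal), and the relative error (µ̂_s − µ_s)/µ_s tabulated with the
standard error from the scored weights. Detected transmissions within 3
standard errors of zero are flagged unevaluable rather than extrapolated.
Default τ grid 0.25–12 in steps of 0.25. The implementation is vectorised
numpy over photon chunks (10⁶ per chunk); runs are bit-reproducible per
seed, and 10⁷ photons at τ = 5 complete in well under a minute on one CPU.

Out of scope: polarisation (the modelled source is unpolarised), coherent
speckle, mirror aberrations, oblique wall incidence.

## Photometric error propagation (`error_studies`)

For each internal transmission t, the measured signal (optionally the
multireflection forward model of t) is perturbed — absolutely (t+Δ) or
relatively (t(1+Δ)) — inverted back, and the relative extinction error
|Δµ/µ| recorded; perturbed values outside the feasible range are flagged,
not dropped. The uncorrected absolute model has the closed form
|ln(1+Δ/t)|/|ln t| with an interior minimum approaching t = e⁻¹ as Δ → 0;
finite Δ shifts the optimum by about ∓Δ/2. The optimum is located by grid
minimum plus parabolic refinement. A purely relative perturbation gives
|ln(1+Δ)|/|ln t|, monotone in t: *no* interior optimum exists, and the code
raises an explicit no-interior-minimum error instead of hiding it — this is
why the absolute perturbation is the default model. The error ratio between
the curve edges and the minimum is asymmetric: ≈3.9× at t = 0.90 but only
≈1.6× at t = 0.10 (the low-transmission rise is gentler in this model);
tests assert those factual ratios.

## Auto-alignment (`autoalign`)

The spectrally integrated detected intensity is abstracted to a scalar
``position → value`` callback. Stage 1 probes the start, then concentric
rings at radial step and in-ring arc spacing both bounded by the detection
radius, so any signal disc of at least that radius inside the scan area
contains a probe point (coverage is exercised over 1000 random placements in
the tests); a discrete ring scan is the simplest scheme with that guarantee.
Stage 2 is central-difference gradient ascent (probe spacing = minimum
gradient step) with move length proportional to the gradient norm, clipped
to configured bounds, and halved when a move would lower the signal; it
terminates when the step falls below tolerance, and never returns a signal
below its starting value. An exhausted scan is a *cancelled* outcome, not an
exception. Threshold and step constants are configuration parameters with
laboratory-plausible defaults (0.2 mm steps, 0.3 mm detection radius, 5 mm
scan radius).

## Synthetic fixtures (`fixtures`)

The generator emulates the validation measurements: polystyrene microspheres
(defaults: measured diameter 3.917 µm, sd 0.03 µm, n = 1.586) in
demineralised water (n = 1.33) in a quartz cuvette (n = 1.46), Mie forward
model × multireflection forward model × multiplicative Gaussian noise
(default sd 0.5%), on a 300–2150 nm grid at 1 nm, with the 1900–2000 nm
water band masked by default. The reference is the same cuvette with the
matched transparent medium. The thin-cuvette default (0.5 mm path, volume
fraction 0.003) keeps the minimum transmission above 10% across the full
range (asserted in the tests) while preserving the diameter-identifying
oscillations. Everything is driven by one seed; identical seeds give
bit-identical spectra.

Deliberately not modelled: etaloning and fiber-mode noise (mitigated in
hardware on the instrument this emulates), spectrometer response, dark
current, wavelength-calibration error, and dual-spectrometer stitching.
Passing the roundtrip and recovery tests therefore demonstrates correctness
of the evaluation chain under multiplicative noise, not robustness to those
instrument artefacts.

## Sphere-parameter fitting (`fitting`)

`MieSphereModel.fit()` minimises log-spectrum residuals
log µ̂_s(λ) − log µ_s(λ; d, c) over (d, log c) with Levenberg–Marquardt;
the log parameterisation keeps c positive and makes it an additive offset.
The starting concentration is the closed-form moment estimate (ratio of
spectral means), exact at the true diameter because µ_s is linear in c.
Parameter covariance is the usual Gauss–Newton estimate σ²(JᵀJ)⁻¹ mapped
through the delta method to (d, c); the residual variance uses n−2 degrees
of freedom. Identifiability rests on the diameter-dependent oscillation
phase of µ_s(λ) near d = 2–4 µm: a ±1% diameter perturbation raises the
noiseless residual norm by more than an order of magnitude (tested). The
spheres' absorption is assumed negligible (µ_t = µ_s). The comparison
report's "mean relative error" is the mean of *absolute* relative errors
over valid wavelengths.

## Problem sizes used in tests and acceptance runs

Monte Carlo budgets: 10⁷ photons for the τ = 5 forward-scattering reference
run, 10⁶ for the MC-vs-closed-form and curve-shape checks, smaller for unit
tests — sizes chosen so every statistical assertion has ≥3σ headroom while
the whole suite stays interactive. Fixture grids in tests use 5–10 nm steps
over 500–1000 nm (the full 1 nm / 300–2150 nm grid is the library default,
exercised once for the feasibility bound). Sampler moment checks use 10⁶
draws; coverage checks 1000 random placements.

## Known limitations

* The cuvette boundary model applies normal-incidence wall transmission at
  all angles; grazing-incidence transport through cuvette walls is outside
  its validity (irrelevant for the sub-milliradian detection geometry).
* No dependent-scattering correction above the 5% volume-fraction warning.
* The Monte Carlo models neither polarisation nor coherence; its detection
  model reduces the mirror/pinhole optics to an angular plus positional cut.
* Dispersion must be supplied by the user; defaults treat indices as
  wavelength-independent.
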