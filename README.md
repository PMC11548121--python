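# collitrans

Toolkit for **broadband collimated transmission spectroscopy** of turbid,
tissue-like media: the forward and inverse optics of the measurement, the
error physics that limits it, and the instrument's auto-alignment search.

Collimated transmission isolates the *ballistic* light that crosses a sample
without being scattered or absorbed. Its decay gives the extinction
coefficient µ_t = µ_a + µ_s [1/mm] through the Beer–Lambert law
µ_t = −(1/cd)·ln(I/I₀). Three effects bias the naive evaluation, and this
package models all of them quantitatively:

1. **Multireflection.** Each refractive-index step of a cuvette reflects
   part of the beam; multiply reflected orders travel a longer path. Summing
   all orders gives geometric-series closed forms for the total transmitted
   and reflected fractions of a slab,

   T_tot = T_I²·T_M / (1 − T_M²(1 − T_I)²),
   R_tot = (1 − T_I) + (1 − T_I)·T_I²·T_M² / (1 − T_M²(1 − T_I)²),

   with T_I the Fresnel interface transmission (a composite wall
   transmission T_G for cuvettes) and T_M = e^(−µ_t d) the single-pass
   internal transmission. Inverting T_tot for T_M corrects the evaluation;
   neglecting it biases weak-absorption measurements by 2r²/(1 − r²)
   (r = 1 − T_G) — about 0.7% for a common glass/water cuvette and >1% for
   higher-index glass.

2. **Forward scattering.** Light scattered into the detection acceptance
   masquerades as ballistic. A Monte Carlo transport model of the
   instrument's low-NA detection arm (pinhole radius / focal length,
   NA ≈ 6.6·10⁻⁴) quantifies this for arbitrary phase functions:
   Henyey–Greenstein p(θ) with exact inverse-CDF sampling, or exact Mie
   phase functions of (poly)disperse microsphere suspensions computed from
   the partial-wave series. What matters is not the anisotropy factor
   g = 2π∫p(θ)cosθ·sinθ dθ but the strength of the first diffraction lobe.

3. **Photometric noise.** A fixed absolute error Δ on the transmission t
   propagates into a relative extinction error |ln(1 + Δ/t)|/|ln t|, which
   diverges at both ends and is minimised near t = 1/e — the practical
   optimum lies between 25% and 50% transmission.

On top of these sit an end-to-end spectrum pipeline (sample/reference CSVs →
masked, multireflection-corrected µ_t(λ) → Mie comparison → sphere-parameter
fit), a seeded synthetic-fixture generator with known ground truth, and the
instrument's two-stage auto-alignment (ring scan with a coverage guarantee,
then adaptive gradient ascent).

## Worked example

Generate a synthetic measurement of 3.917 µm polystyrene spheres
(volume fraction 0.003, 0.5 mm quartz cuvette, 0.5% multiplicative noise),
evaluate it, and fit the sphere parameters starting from the nominal
diameter 3.97 µm:

```python
import numpy as np
import collitrans as ct

spec = ct.FixtureSpec(wavelength_nm=np.arange(500.0, 1000.0, 5.0),
                      noise_sd=0.005, masked_intervals_nm=(), seed=11)
fx = ct.generate_measurement_pair(spec)
mu = ct.extinction_spectrum(fx.sample, fx.reference, spec.cuvette)
res = ct.fit_sphere_parameters(
    mu, spec.suspension.replace(diameter_um=3.97, volume_fraction=0.002))
print(res.summary())
```

```
Mie sphere-suspension fit
======================================================
observations          100
residual norm (log)   5.5651e-02
function evaluations  7
------------------------------------------------------
parameter               estimate       std err
diameter_um             3.916434      1.28e-03
volume_fraction     2.999879e-03      2.01e-06
======================================================
```

The fitted diameter recovers the ground truth 3.917 µm well within one
standard error, and the concentration to 4·10⁻³ %; the subsequent
`ct.compare_to_mie(mu, ...)` report shows a mean |relative error| of 0.43%
against the fitted Mie spectrum, consistent with the injected 0.5% noise.

The same flows are scriptable from the shell:

```sh
collitrans make-fixture --config fixture.yaml --out-dir fx/
collitrans evaluate --sample fx/sample.csv --reference fx/reference.csv \
    --config cuvette.yaml --out mu_t.csv
collitrans fit-spheres --measured mu_t.csv --config suspension.yaml
collitrans error-study --model absolute --magnitude 0.01 --out curve.csv
collitrans mc-transmission --config scene.yaml --out mc.csv
collitrans autoalign-sim --map map.csv --threshold 0.5
```

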