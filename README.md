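# sandix

Gray-matter diffusion MRI microstructure modelling with water exchange:
powder-averaged compartment models (SANDI, SMEX, SANDIX, eSANDIX), a
generalized two-pool Kärger exchange engine, multi-start model fitting
with variable projection and BIC comparison, MR-radius/permeability
analysis, and a Monte Carlo restricted-diffusion simulator.

## The problem

Powder-averaged (spherical-mean) diffusion MRI signals from cortical
gray matter mix three sources — extracellular water, neurites
(dendrites and axons, well described as zero-radius "sticks"), and cell
bodies (somas, spheres in the Gaussian phase approximation).  Two
functional signatures disambiguate competing tissue models:

1. **The stick power-law.**  Impermeable sticks give
   S̄ ∝ √(π/(4bDn)) · erf(√(bDn)) → b^(−1/2) at large b.  Somas obscure
   it, and neurite–extracellular water exchange breaks it: the
   large-b expansion of the exchanging system is
   S̄ ~ fn √(π/(4bDn)) e^(−t·rn) (1 + t·rn(2 + t·re)/(b·De)),
   so the amplitude is attenuated by the non-exchanged volume fraction
   e^(−t·rn) while the b^(−1/2) scaling is approached slower than
   exponentially.
2. **The sign of the time dependence at fixed b.**  For the Kärger
   system dS/dt ≤ 0 for *every* parameter choice (exchange ⇒ signal
   decreases with diffusion time), whereas non-exchanging restricted
   compartments have dS/dt ≥ 0 (their apparent diffusivity decreases
   with time).  The sign of S(Δ) at fixed b therefore reports whether
   exchange or structure dominates.

The package implements these models and signatures for PGSE encodings
(b, Δ, δ), the fitting protocol to estimate
(fe, fn, fn_imp, fs, fim, De, Dn, τn, Rs), and a particle simulator in
parametric geometries that serves as an independent oracle for the
analytic expressions.  It is aimed at researchers modelling
ROI-averaged powder signals at strong diffusion weighting and multiple
diffusion times.  See `docs/methods.md` for the full model description.

## Worked example

Generate a noisy synthetic dataset from an eSANDIX ground truth at the
built-in ex vivo acquisition (δ = 4.5 ms, Δ ∈ {7.5, 11, 16} ms, b up to
100 ms/µm², 10/30 averages, 30 directions, 1% Rician noise), fit the
model with 50 random starts, and classify the time dependence:

```python
import sandix as sx

truth = sx.GmModelParams(model_id="eSANDIX", fe=0.40, fn=0.38,
                         fn_imp=0.05, fs=0.16, fim=0.01,
                         De=0.85, Dn=0.5, tau_n=4.0, Rs=12.5)
table, _ = sx.generate_dataset(sx.SyntheticSpec(params=truth, sigma=0.01,
                                                seed=42))
print(sx.time_dependence_sign(table, b_min=5.0))

res = sx.fit_model(table, "eSANDIX", n_starts=50, seed=3)
p = res.best.params
print(f"tau_n = {p['tau_n']:.2f} ms  Dn = {p['Dn']:.2f}  "
      f"fe = {p['fe']:.2f}  Rs = {p['Rs']:.1f} um")
print(f"cost = {res.cost:.3g}  BIC = {res.bic:.1f}  "
      f"basins = {len(res.minima)}")
```

Output:

```
decreasing
tau_n = 4.02 ms  Dn = 0.45  fe = 0.42  Rs = 12.6 um
cost = 2e-05  BIC = -937.2  basins = 6
```

The classification is "decreasing" because exchange dominates the time
dependence of this ground truth; the fit recovers the 4 ms neurite
residence time to within ~1% and the remaining parameters to within the
noise-limited accuracy.  The additional basins are genuine alternative
minima of the model (notably a competing solution with smaller soma
radius), ranked by cost in `res.minima`.

A command-line interface mirrors the library
(`sandix simulate-signal | generate | fit | exponent | time-sign |
mc-sim | radius | permeability`).

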