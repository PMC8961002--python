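# Methods

This note describes the models, numerical methods and design choices
behind `sandix`: a toolkit for powder-averaged (spherical-mean) diffusion
MRI signal models of gray matter with and without neurite-extracellular
water exchange, together with the fitting machinery and a Monte Carlo
restricted-diffusion simulator used as an independent oracle.

## Units and conventions

Times are in ms, lengths in um, b-values in ms/um^2, diffusivities in
um^2/ms, exchange rates in 1/ms, permeabilities in um/s.  A PGSE
encoding is parameterized by (b, Delta, delta) with ideal rectangular
pulses (ramp times neglected), so the dephasing wave vector q(t) is the
piecewise-linear trapezoid with plateau q0 = sqrt(b/(Delta - delta/3)).
The gyromagnetic ratio appears only when a physical gradient amplitude
is requested.

## Signal models

All models describe the powder-averaged signal S(b, Delta, delta)/S0 as
a sum of compartment signals weighted by signal fractions that sum to
one (a b- and time-independent immobile-water offset `fim` is included
in the sum):

- **Extracellular water** — isotropic Gaussian, `exp(-b De)`.
- **Neurites** — sticks (zero-radius cylinders).  The powder average of
  `exp(-b Dn eps^2)` over orientation cosines eps in [0, 1] is
  `sqrt(pi/(4 b Dn)) erf(sqrt(b Dn))`, with the `b^(-1/2)` power law as
  its large-b asymptote.  Below `b*Dn = 1e-6` a two-term Taylor series
  avoids 0/0.
- **Somas** — spheres of radius Rs in the Gaussian phase approximation
  (GPA): `exp(-b Ds(Delta, delta, Rs))`.  `Ds` is the Neuman/Murday-Cotts
  eigenmode sum over roots of `J_{3/2}(a) = a J_{5/2}(a)` (equivalently
  the Neumann condition `a J_{1/2} = 2 J_{3/2}`).  The narrow-pulse
  expression uses the exact identity
  `sum_m 1/(alpha_m^2 (alpha_m^2 - 2)) = 1/10` so only exponentially
  suppressed terms are truncated; the finite-pulse sum uses M = 50
  cached roots (bracketed Brent iterations, 1e-12 tolerance), for which
  doubling M changes Ds by less than 1e-8 anywhere on
  Delta in [5, 30] ms, R in [1, 20] um.  The intrasoma free diffusivity
  is fixed at D0 = 2 um^2/ms; the GPA is applied at all b, which is
  adequate because the soma signal is strongly attenuated wherever the
  GPA degrades (validated against Monte Carlo below).

The four model variants are: **SANDI** (extracellular + stick + sphere +
offset, no exchange), **SMEX** (stick exchanging with the extracellular
pool, no explicit soma), **SANDIX** (SMEX plus an impermeable soma), and
**eSANDIX** (SANDIX plus a non-exchanging stick sub-population that
shares Dn with the exchanging sticks — the myelinated-axon surrogate).
SMEX and SANDIX bracket the fully-permeable and impermeable soma limits.

## Exchange engine

Exchange between one stick population and the extracellular pool is
modelled with the two-compartment Karger system generalized to arbitrary
gradient waveforms:

    d/dt [S1; S2] = ([-r1 r2; r1 -r2] - q^2(t) diag(D1, D2)) [S1; S2]

from initial state [f1; f2], with detailed balance r1 f1 = r2 f2 and the
stick's apparent diffusivity D1 = Dn eps^2 per orientation.  The powder
average over eps uses 64-node Gauss-Legendre quadrature on [0, 1]
(order-doubling changes the result by < 1e-6 at b = 100; the integrand
peaks near eps = 0 at large b).  Spins are assumed to visit a single
neurite during the encoding, which partitions the tissue into
orientation-differing cells with identical powder averages.

Two evaluation paths exist:

1. **Reference ODE path** — adaptive DOP853 with rtol 1e-9/atol 1e-12 and
   analytic q^2(t) (no interpolation error); validated against a 1e4-step
   product of exact matrix exponentials on a midpoint-discretized q^2(t)
   to better than 1e-8.
2. **Fast PGSE path** — the encoding is split into ramp-plateau-ramp
   segments; the plateau propagator is one exact 2x2 matrix exponential
   and each ramp is midpoint-sampled (second order).  A Richardson step
   combining ramp subdivisions n and n/2 removes the leading error term
   (fourth order), giving ~1e-8 agreement with the ODE at n = 32 while
   evaluating whole (b-grid x quadrature-node) blocks vectorized.  Both
   eigenvalues of the generator are nonpositive, so the propagator is
   evaluated through exp((m +/- d) h) <= 1 and cannot overflow for any
   exchange rate.  Model evaluation uses n = 32; fitting uses n = 16
   (error ~4e-7, far below noise and the fit tolerances).

Closed forms implemented alongside the solver:

- **Narrow-pulse solution** `S = fp1 e^{-a1} + fp2 e^{-a2}` with
  `a_{1,2} = (bD1 + bD2 + t r1 + t r2 +/- s)/2`,
  `s = sqrt((bD1 - bD2 + t r1 - t r2)^2 + 4 t^2 r1 r2)` and weights
  `fp_{1,2} = +/-(b Dbar - a_{2,1})/(a1 - a2)`.  It is evaluated as
  `0.5 (e^{-a1}+e^{-a2}) - u (e^{-a2}-e^{-a1})/s`, `u = b Dbar - abar`,
  which is overflow-free and covers the degenerate a1 = a2 limit.
  The effective diffusion time of PGSE is identified with Delta.
- **Large-b series.**  Laplace's method on the orientation integral of
  the narrow-pulse solution gives, to order b^(-3/2),

      S ~ fn sqrt(pi/(4 b Dn)) e^{-t rn} (1 + t rn (2 + t re)/(b De)).

  The derivation was done symbolically (series expansion in 1/b of the
  orientation integrand) and verified against the numerically integrated
  closed form: b*(S_quad/S_series - 1) agrees to four digits across
  parameter sets.  Exchange attenuates the power-law amplitude by the
  non-exchanged volume fraction `e^{-t rn}`; all corrections are higher
  order in b, so the `b^{-1/2}` scaling survives exchange, only
  approached slower than exponentially.
- **Time derivative (exchange signature).**  Differentiating the
  closed form exactly yields

      dS/dt = -(1/2) f1 r1 (bD2 - bD1)^2 e^{-(a1+a2)/2}
              (h cosh h - sinh h)/h^3,   h = s/2,

  which is nonpositive for every parameter choice: at fixed b the
  exchanging signal always decreases with diffusion time.  Gaussian
  restricted compartments behave oppositely (their apparent diffusivity
  decreases with time, so `f exp(-b D(t))` increases), which provides
  the exchange-vs-structure classification implemented in
  `time_dependence_sign` (strict per-b comparison across Delta with a
  configurable relative dead-band, default 0.5%, matching the ~1%
  residual noise floor of averaged data; noiseless model comparisons use
  a zero dead-band).  The prefactor 1/2 and the argument h = s/2 were
  fixed by symbolic differentiation and a finite-difference match to
  1e-6 relative on random parameter grids.
- **Quadratic rate estimate.**  At one large b-value,
  `ln(S(t0+t)/S(t0))` fitted as `-c1 t - c2 t^2` gives
  `rn = c1 - 2 t0 c2` with residual relative bias of order 2/(b De)
  (the t0-dependent terms cancel exactly under the series above).

## Fitting

Nonlinear least squares with variable projection: the nonlinear
parameters are the diffusivities, the exchange rate rn (bounded to
[0, 1] /ms and reported as tau_n = 1/rn), the soma radius Rs in
[0, 20] um and the relative fraction of the exchanging pair (the signal
is nonlinear in that split); all compartment amplitudes (including the
overall scale S0) are eliminated at every residual evaluation by
bounded nonnegative linear least squares (BVLS; rank-deficient designs
fall back to a small ridge and are flagged).  The immobile-water
amplitude is capped at 0.05, reflecting the sub-1% estimates this
offset takes in practice.  Residuals are unweighted.

Each fit runs from `n_starts` random initializations (diffusivities
uniform on 0-3 um^2/ms, rate on 0-1 /ms, radius on 0-20 um, pair split
on 0-100%) through a bounded trust-region optimizer (ftol/xtol/gtol
1e-12); non-finite model values during the search yield large residuals
rather than crashes.  Converged solutions are clustered into basins
(1% relative per-parameter tolerance with small absolute floors) and
reported with basin occupation counts; the default start count is 1000
for production use, while the tests use 20-50 for speed.  Models are
compared by `BIC = n ln(cost/n) + k ln n` computed identically across
models; differences above 10 are flagged significant and below 1
indistinguishable.

The landscape genuinely has competing minima: on noisy data the
soma/extracellular near-degeneracy produces an alternative basin with
smaller Rs, larger neurite fraction and near-free extracellular
diffusivity, which the minima enumeration reports rather than hides.

## MR radius and permeability

For a gamma distribution of soma radii (shape (mean/sd)^2, scale
sd^2/mean) the closed-form moments give small-soma MR-radius estimators
(`(<R^6>/<R^2>)^(1/4)` for thin cylinders, `(<R^7>/<R^3>)^(1/4)` and
`(<R^5>/<R^3>)^(1/2)` for small spheres with wide/narrow pulses).  The
general-radius "expected MR radius" averages the narrow-pulse sphere
diffusivity over the distribution with R^3 volume weighting (adaptive
quadrature on [0, mean + 8 sd], tolerance 1e-9) and inverts the
monotone map R -> Ds(R) at Delta = 16 ms, D0 = 2 um^2/ms.  An
alternative signal-weighted definition (average exp(-b Ds) then invert)
is available behind a flag; the two agree as b -> 0, and the
diffusivity-weighted variant is the default.  All estimators exceed the
distribution mean for any positive variance.  Permeability follows from
the well-mixed relation for a cylinder, P = R/(2 tau) (S/V = 2/R).

## Monte Carlo simulator

Particles start uniformly inside an analytic geometry — sphere, finite
cylinder, undulating cylinder (tube of radius R around a sinusoidal
centerline, z-plane cross-sections), or a ball-and-sticks toy neuron
(soma sphere with radially attached finite cylinders of uniformly
random orientation) — and take isotropic Gaussian steps with per-axis
std sqrt(2 D0 dt), dt = sigma^2/(6 D0).  Boundary crossings are located
by bisection along the step and resolved as elastic collisions with the
local tangent plane (closed-form normals; the reflection is iterated up
to 10 times and the rare failures are counted and reported, never
silently dropped).  Per-particle RNG streams are xorshift64-class
generators seeded by a splitmix hash of (run seed, particle id), so
results do not depend on execution order.  A post-run containment check
asserts no particle escaped, and a chi-square test on equal-volume bins
verifies that reflection preserves the uniform equilibrium density.

PGSE signals use the midpoint phase integral: during the walk each
particle accumulates the 3-vector `P = sum_k qhat(t_k) dx_k` per
(Delta, delta) timing, where qhat is the unit-amplitude profile; the
signal at any b and direction d is then `<cos(q0 P . d)>`, powder
averaged over >= 30 Fibonacci-hemisphere directions.  One trajectory
set therefore serves every b-value and direction, and several timings
share trajectories when their encodings fit the run duration.

The soma/neurite split of ball-and-sticks runs labels particles
starting farther than `R_soma + 2 sqrt(2 D0 t)` from the center as
neurite (negligible probability of reaching the soma within t); the
fraction of soma-labelled particles outside the geometric soma
("in between") is reported and stays below ~10% at the acquisition
timings.

**Scale.**  Production-grade simulations in the literature use ~1e6
particles at sigma = 0.01 um; the package's defaults (sigma = 0.05 um,
1e4-1e5 particles) are chosen so a thin-cylinder run at the acquisition
timings completes in about two minutes on one core.  Convergence is
demonstrated by the step-halving property (halving sigma changes
signals by < 1% for b <= 100) rather than brute force.  At this scale
the analytic ball-and-sticks neuron reproduces the robust qualitative
features — near-1/2 neurite exponent, neurite dominance of the total
signal at the largest b — but its soma (ADC ~0.75 um^2/ms at R = 8 um,
Delta = 16 ms) is essentially fully attenuated beyond b = 10, so the
soma-driven steepening of the total-signal exponent seen with mesh
neurons at full scale is not reproduced; soma-labelled particles
instead retain stick-like signal from attached neurites.

## Synthetic data

The generator emulates the ex vivo measurement: the ground-truth model
signal per protocol row (delta = 4.5 ms; Delta = 7.5, 11, 16 ms; seven
low-b shells plus high-b grids linear in b^(-1/2) of 11/12/21 points,
reaching b = 100 ms/um^2 at Delta = 16 ms), Rician magnitude noise per
average (ten averages for b <= 25 ms/um^2, thirty above), averaging,
and inversion of the Rician first moment
`E[M] = sigma sqrt(pi/2) [(1+x) I0(x/2) + x I1(x/2)] e^{-x/2}`,
x = nu^2/(2 sigma^2) (scaled Bessel evaluation; magnitudes at the
noise floor clamp to zero with a warning).  The default per-direction
mode mirrors the acquisition's thirty gradient directions: the
synthetic voxel is modelled as fully orientation-dispersed (no ODF), so
each direction's expectation is the powder mean and the mode amounts to
direction-wise correction before the powder average, exactly the order
of operations of the real pipeline.  A simpler powder-level noise mode
is available.  Noise sigma is an input (estimating it from data is out
of scope).  What passing recovery tests show is therefore robustness to
magnitude noise and averaging structure — not to orientation-dispersion
mismatch, residual artifacts, or spatial effects, which the generator
does not emulate.

## Known limitations

- The Karger description is barrier-limited; at the fast exchange rates
  the models can report (tau_n of a few ms) its validity is assumption,
  not consequence.
- No oscillating or general gradient waveforms are constructed (the ODE
  engine accepts any piecewise q(t), but only PGSE encodings are built).
- The extracellular compartment is isotropic; anisotropic extensions are
  deliberately excluded.
- Monte Carlo membranes are impermeable; exchange is never simulated,
  only modelled.
- Voxelwise map fitting, denoising, registration and other image-domain
  preprocessing are out of scope; the package operates on ROI-averaged
  powder curves.
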