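# Methods

## Model family

The receptive-field model is the generalized (affine) Gaussian derivative
family. A purely spatial simple-cell kernel of order m is

    T_m(x; σ₁, σ₂, φ) = σ₁^m ∂_φ^m g(x; Σ_φ),

with g the 2-D Gaussian of covariance Σ_φ, whose eigenvalues are σ₁² (along
the unit vector (cos φ, sin φ)) and σ₂² (orthogonal). The elements of Σ_φ are

    C₁₁ = σ₁² cos²φ + σ₂² sin²φ,
    C₁₂ = (σ₁² − σ₂²) cos φ sin φ,
    C₂₂ = σ₁² sin²φ + σ₂² cos²φ.

The scale-normalization factor is σ₁^m, the standard deviation *along the
derivative direction* φ. This identification matters: it is the convention
under which the frequency-maximized tuning curves collapse exactly to the
frequency-free closed forms below. The directional derivative is evaluated
analytically in rotated coordinates (u along φ, w orthogonal):
σ₁^m ∂_u^m g = (−1)^m He_m(u/σ₁) g, with He_m the probabilists' Hermite
polynomial. Finite differences appear only as an independent test oracle
(4th-order-accurate central stencils at step σ₁/16), never in the
computation.

Spatio-temporal kernels multiply a temporal Gaussian h(t; σ_t) in a frame
moving with velocity v parallel to φ, with a velocity-adapted temporal
derivative (∂_t + v·∇)^n and normalization σ_t^n. Because the adapted
derivative leaves the moving-frame spatial argument invariant, the kernel
factorizes analytically into the spatial kernel at (x − vt) times the n-th
normalized derivative of h. The temporal kernel is non-causal by
construction; time-causal smoothing is out of scope.

Complex cells are modelled by the quasi-quadrature energy measure

    Q = √(L₁² + C_φ L₂²),      default C_φ = C_t = 1/√2,

over the order-1 and order-2 responses, an affine-Gaussian analogue of the
classical energy model built from approximate quadrature pairs.

## Orientation-selectivity curves

A kernel with φ = 0 is probed with sine gratings of inclination θ. The
response amplitude of the order-m kernel has the analytic form

    A_m(ω, θ) = (σ₁ ω |cos θ|)^m exp(−ω² s(θ)/2),
    s(θ) = σ₁² cos²θ + σ₂² sin²θ,

and for spatio-temporal kernels an additional temporal transfer factor at the
Doppler-shifted frequency ω(e_θ·v − u), which is unity when the probe speed u
matches the receptive-field velocity projected on the grating normal — the
default probe convention, under which n = 0 spatio-temporal curves equal the
purely spatial ones.

The selectivity curve is defined as the amplitude at the per-θ optimal
frequency, ω*² = m/s(θ), normalized by the θ = 0 value. This is the unique
convention that removes all ω dependence and yields

    r_m(θ) = (|cos θ| / √(cos²θ + κ² sin²θ))^m,   κ = σ₂/σ₁,

for m = 1..4, the same expression with exponent 3/2 for the complex-cell
model (equivalently r_c = √(r₁ r₂)), and the general power family r_λ. The
`sampled` mode measures the same curve from the discrete Fourier integral of
the sampled kernel at the grating wave vector — exactly the amplitude of the
discrete convolution of kernel and grating — with a bounded scalar search
over ω bracketing the analytic optimum. An aliasing guard rejects gratings
above 80% of the grid Nyquist frequency.

**Quasi-quadrature curves are approximate.** Phase is aggregated by combining
per-order amplitudes, Q = √(A₁² + C_φ A₂²), and maximizing over ω. The
normalized curve of this construction depends on κ only through r₁, so its
deviation from the exponent-3/2 closed form is a fixed property of the
construction; we measured a maximum absolute deviation of 0.062 (at C_φ =
1/√2, any κ), and the numeric test asserts the 0.07 bound. The exact
relationship is the algebraic factorization r_c = √(r₁ r₂), which is tested
to 1e−12 and used everywhere downstream.

## Resultant statistic

Tuning sharpness is summarized by the circular resultant under the
double-angle mapping, R = ∫ r e^{2iθ} dθ / ∫ r dθ, integrated over one
period (the curves are π-periodic, so the half-period ratio equals the
full-period one). Closed forms in κ exist for the integer orders:

    |R|₁ = κ(κ acosh κ − √(κ²−1)) / ((κ²−1) acosh κ),
    |R|₂ = κ/(κ+1),
    |R|₃ = κ(√(κ²−1)(κ²+2) − 3κ acosh κ) / ((κ²−1)(κ√(κ²−1) − acosh κ)),
    |R|₄ = κ(κ+3)/((κ+1)(κ+2)).

Numerical choices:

- **κ < 1 branch.** The populations span κ ∈ [1/κ_max, κ_max], but the
  inverse-cosh forms are written for κ > 1. They are continued with
  acosh κ → arccos κ and √(κ²−1) → √(1−κ²); the imaginary factors cancel and
  the result is real. Validated against quadrature to 1e−12.
- **κ = 1.** Orders 1 and 3 have removable singularities; within |κ−1| < 1e−4
  the value is delegated to quadrature (and exactly λ/(λ+2) at κ = 1).
- **Complex cells.** Quadrature is the default. An equivalent closed form was
  derived via the Euler integral of the Gauss hypergeometric function
  (substituting t = sin²θ):
  |R| = 1 − 2 B(3/2,5/4) ₂F₁(3/4,3/2;11/4;1−κ²) / (B(1/2,5/4) ₂F₁(3/4,1/2;7/4;1−κ²)).
  It is enabled by `use_hypergeometric=True`, is cross-validated against
  quadrature to ~1e−11, and is used (for speed, as a vectorized ufunc) in the
  population simulation of the complex-cell class.

## Population simulation

Defaults are the study conditions: κ_max = 8, log-uniform κ (equivalently
uniform K = log κ on [−log 8, log 8]), 10,000 cells per class, 10 equal-width
bins on [0, 1] (right-open except the last), equal neuron counts across
orders when combining. Grid sampling (equally spaced K including endpoints)
makes the pipeline bit-reproducible; random mode draws i.i.d. uniform K under
a seed. The number of simulated cells and the bin count are this package's
choices — large enough that the structural findings (the first-order class is
bounded by |R| ≤ 0.652 < 0.7; exactly half of the second-order cells exceed
|R| = 1/2 on a symmetric grid; the up-to-order-4 mixture alone populates the
top bin) are not sampling artifacts. Samples with κ < 1 are retained, not
folded to 1/κ. Comparison with biological resultant histograms is qualitative
(mode position, tail mass), never a fitted distance.

## Tuning-curve fitting

Fits minimize unweighted least squares of r_λ(θ; e^K) against normalized
responses over (λ, K = log κ), or K alone with λ fixed to a known order. No
noise model is imposed on the data. Initialization from the curve's slope
near θ = 0 is unstable, so a coarse grid (λ ∈ [0.5, 6] × K ∈ [−log 8, log 8],
12 × 17 points, ties broken by lowest residual) seeds
`scipy.optimize.least_squares`. With λ free there is a mild (λ, κ) trade-off
under noise; recovery experiments (λ = 2, κ = 3, additive Gaussian noise
SD 0.02 on 181 angles, 100 seeds) give a median relative error in κ̂ below
10%, and noiseless fits are exact to 1e−6. Both free-λ and fixed-λ modes are
provided because it is an open question whether biological fits should
restrict λ to the integer derivative orders.

The synthetic-curve generator adds i.i.d. Gaussian noise to the exact closed
form and clips at zero. It emulates trial-averaged, normalized tuning
measurements; it does not model multiplicative (Poisson-like) spiking noise,
baseline offsets, tuning asymmetries or fit-window truncation, so recovery
results bound estimator behaviour under idealized noise only.

## Synthetic pinwheel maps

Orientation maps are synthesized by superposing half-winding singularities:
φ(x) = Σ_j s_j arg(x − c_j) mod π with s_j = ±1/2, giving exactly ±π of
orientation advance around any loop enclosing one center. Centers are drawn
uniformly (rejecting draws closer than 2 lattice steps); this tests the
measurement logic, not map development — no self-organizing dynamics are
simulated, and real maps' quasi-periodic column spacing is not reproduced.
Elongation is assigned radially, κ(d) = 1 + (κ_max − 1) d/d_max by default,
isotropic (κ = 1, ε = 1) at each center — the configuration in which tuning
is broadest at pinwheel centers. Only the ratio κ is modelled; how the two
absolute scale parameters individually vary is left unspecified.

Orientation homogeneity H of a site is the modulus of the mean of e^{2iφ}
over neighbours within a radius (default 3 lattice steps, site excluded).
The double-angle resultant is the natural π-periodic choice and mirrors the
tuning-curve statistic; the diagnostics name H without fixing a formula, so
this definition is a package decision. Site selectivity is the closed-form
|R| at the site's κ with exponent λ = 2 by default. Distances are Euclidean
in lattice units. All diagnostics are bit-reproducible under a fixed seed.

## Interfaces

All artifacts are CSV (header row, full double precision) with JSON metadata
sidecars recording the complete parameter set including seeds, so every table
is regenerable from its sidecar. The `affinerf` CLI exposes the six
subcommands (`kernel`, `tuning`, `resultant`, `population`, `fit`,
`cortmap`); a YAML config can supply defaults for parameters not given on the
command line. Plots are not generated; every figure-style result is exported
as its underlying table.

## Known limitations

- The quasi-quadrature numeric curve approximates the exponent-3/2 closed
  form only to ~0.06; the closed form is authoritative downstream.
- Spatio-temporal tuning with temporal derivative order n ≥ 1 under the
  matched-velocity probe convention is degenerate (the Doppler factor
  vanishes); curves for such cells require an explicitly mismatched probe.
- The affine-covariance check is a discretized commutation test; its
  tolerance (1e−3 of peak) reflects interpolation and truncation error, not
  model error.
- No analysis of real neurophysiological recordings is included; fits expect
  pre-normalized tuning curves.
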