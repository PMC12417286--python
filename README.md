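# affinerf

Orientation selectivity of affine Gaussian derivative receptive fields.

Visual neurons in the primary visual cortex respond selectively to the
orientation of a stimulus, and the sharpness of that selectivity varies widely
across neurons. `affinerf` implements an idealized model family in which this
variability arises from the *elongation* of the receptive fields: simple cells
are modelled as scale-normalized directional derivatives of anisotropic
(affine) Gaussian kernels,

    T_m(x) = σ₁^m ∂_φ^m g(x; Σ_φ),        m = 1, …, 4,

where the covariance Σ_φ has standard deviations σ₁ along the preferred
orientation φ and σ₂ orthogonal to it, with elongation κ = σ₂/σ₁ and
eccentricity ε = 1/κ. Complex cells are modelled by a quasi-quadrature energy
measure √(L₁² + C_φ L₂²) over the first two derivative orders. The package is
aimed at computational neuroscientists who want to connect measured
orientation-tuning curves and tuning-sharpness statistics to receptive-field
shape parameters.

## What it computes

- **Kernels** (`rf_kernels`): analytic sampling of the spatial and
  spatio-temporal derivative kernels, and a numerical verification that the
  family is covariant under affine image transformations (smoothing commutes
  with warping when Σ ↦ AΣAᵀ).
- **Tuning curves** (`tuning`): the response amplitude of a kernel to a sine
  grating of inclination θ, maximized over spatial frequency and normalized at
  θ = 0, both measured from sampled kernels and in closed form

      r_λ(θ) = ( |cos θ| / √(cos²θ + κ² sin²θ) )^λ,

  with λ = m for simple cells and λ = 3/2 for the complex-cell energy model.
- **Resultant statistic** (`resultant`): the circular resultant
  R = ∫ r(θ) e^{2iθ} dθ / ∫ r(θ) dθ, the standard double-angle measure of
  tuning sharpness (|R| → 1: sharp; 1 − |R| is the circular variance), by
  quadrature and by closed forms in κ for every model class.
- **Population histograms** (`population`): distributions of |R| over
  populations with log-uniform elongation κ ∈ [1/κ_max, κ_max] (default
  κ_max = 8), per derivative order and for mixtures of orders.
- **Elongation estimation** (`fitting`): nonlinear least-squares fits of
  r_λ(θ; κ) to measured (or synthetic noisy) tuning curves, returning
  (λ̂, κ̂, ε̂).
- **Pinwheel-map diagnostics** (`cortical_map`): synthetic orientation maps
  built from half-winding singularities with a radial eccentricity profile,
  and the per-site joint measurements (distance to the nearest pinwheel
  center, eccentricity, orientation homogeneity H, selectivity |R|) proposed
  for testing whether elongation increases away from pinwheel centers.

## Worked example

The resultant of a second-order simple cell with elongation κ = 2, from the
command line:

```sh
$ affinerf resultant --model simple --order 2 --kappa 2
0.666667
```

(the closed form κ/(κ+1) = 2/3; the first-order and complex-cell models at the
same κ give 0.4565 and 0.5805). A population simulation and an elongation fit
from Python:

```python
>>> import affinerf as rf
>>> spec = rf.PopulationSpec(kappa_max=8.0, n_per_class=10_000, sampling="grid")
>>> hists = rf.simulate_histograms(spec)
>>> rf.combine_orders(spec, 2, hists).counts
array([ 929, 3776, 2802, 2412, 2371, 2620, 2127, 1296, 1667,    0])
>>> rf.combine_orders(spec, 4, hists).counts
array([ 929, 5347, 5261, 4377, 4122, 4311, 3896, 3343, 4529, 3885])
```

Both mixtures have their mode at low |R| (bin [0.1, 0.2)), but only the
mixture including third- and fourth-order cells puts mass in the top bin
[0.9, 1.0] (3885 of 40,000 cells here, versus none up to order 2): higher
derivative orders produce sharply tuned cells even at moderate elongation.
Fitting a noisy synthetic curve recovers the generating parameters:

```python
>>> curve = rf.generate_synthetic_tuning(kappa=3.0, lam=2.0, noise_sd=0.02, seed=7)
>>> fit = rf.fit_tuning(curve)
>>> round(fit.lambda_hat, 3), round(fit.kappa_hat, 3)
(2.033, 2.979)
```

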