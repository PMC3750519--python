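# Methods

## Model

The package ships one concrete reaction–diffusion system, chosen as a
minimal mechanistic picture of how an immobilized chemokine gradient forms
around a lymphatic vessel.  Three fields live on the unit square
Ω = [0, 1]² (dimensionless space and time throughout):

* `p(t, x)` — freely diffusing signaling protein (e.g. CCL21), released at
  rate α inside a vessel-shaped region Q ⊂ Ω, diffusing with coefficient D
  and degraded at rate γ;
* `s(t, x)` — immobile binding substrate (extracellular-matrix sugars),
  initial level s₀ ≡ 1 after nondimensionalization;
* `c(t, x)` — the immobilized protein–substrate complex, the species that
  antibody stainings visualize.

```
∂ₜp = D Δp + α Q − k₁ p s + k₋₁ c − γ p
∂ₜs =            − k₁ p s + k₋₁ c
∂ₜc =              k₁ p s − k₋₁ c
```

with p(0,·) = c(0,·) = 0, s(0,·) = s₀, and no-flux (homogeneous Neumann)
boundaries for the only diffusing species p.  The five kinetic unknowns are
θ = (D, α, k₁, k₋₁, γ), each constrained a priori to [10⁻², 10¹].

The source Q is the indicator of a y-shaped union of three thickened
segments (stem (0.5, 0.05)→(0.5, 0.45), branches to (0.25, 0.95) and
(0.75, 0.95), half-width 0.05).  These geometry values are a package
default — the shape imitates a vessel branch, but nothing in the science
pins down the exact coordinates — and all five of them are configurable.
Q is treated as constant in time.

## Observation and noise model

An image is a grid of M pixels; pixel i at acquisition time t_k reports

```
y_{k,i} = b + ∫_{A_i} c(t_k, x) dx
```

with a constant background offset b ≥ 0.  The package defaults to a 10 × 5
tiling of the whole domain (M = 50 equal pixels of area 0.02); the tiling
is a package choice and configurable, with pixels required to align with
grid-cell boundaries so the quadrature (midpoint rule over cells) is
unambiguous and exact for per-cell-constant fields.

Measured intensities are strictly positive counts, so noise is
multiplicative log-normal: ȳ = ε·y with log ε ~ N(0, σ²) i.i.d. per pixel
and time point.  The benchmark scenario uses σ = 10⁻² — read as the
standard deviation of the log intensity, i.e. σ² = 10⁻⁴; roughly 1%
multiplicative noise — and b = 10⁻⁴.  The strictly positive offset matters
twice: it keeps log ȳ defined for pixels far from the source, and it is the
natural floor under which no kinetic signal survives.

## Likelihood

With N time points and M pixels the negative log-likelihood is

```
J(θ) = Σ_{k,i} [ log(√(2π) σ ȳ_{k,i}) + (log ȳ_{k,i} − log y_{k,i}(θ))² / (2σ²) ]
```

the standard log-normal density.  At fixed kinetics the inner maximization
over σ² is closed-form — σ̂² equals the mean squared log-residual — so σ²
is profiled analytically and never optimized numerically (a configurable
floor of 10⁻¹² guards the exact-fit degeneracy).  The offset b is treated
as known by default; it can be freed by fitting templates with different
values.

## Forward solver

Space: uniform cell-centered grid (default 50 × 50), 5-point Laplacian,
Neumann boundaries by ghost-cell reflection.  Cell-centering puts every
node strictly inside Ω and makes the reflection exact; constants lie in the
stencil's null space, so a uniform field does not diffuse.

The reaction part conserves s + c pointwise (∂ₜ(s+c) = 0), so the substrate
is eliminated exactly before integration: only (p, c) are integrated and
s(t,x) = (s(0,x)+c(0,x)) − c(t,x).  This shrinks the ODE system by a third
and makes the conservation invariant hold to machine precision by
construction; it is an exact algebraic reduction, not an approximation.

Time: stiff-capable implicit method of lines (`solve_ivp` BDF) with an
analytic sparse Jacobian; defaults rtol 10⁻⁸, atol 10⁻¹⁰.  The binding rate
k₁ = 5 against the sub-unit time scale makes the system moderately stiff;
explicit integrators waste steps on the fast binding equilibration.  A
failed solve raises a `SolverFailure` carrying the parameter vector; inside
the objective this becomes a +∞ sentinel so optimizers treat the point as
infeasible and continue.

The binary source limits spatial convergence at its edge; for convergence
studies the package provides analytically smooth sources (a Gaussian bump,
or a soft-edged vessel whose indicator decays as a Gaussian of the distance
beyond the half-width).  These are defined as functions of space, not by
filtering the rasterized indicator, so refinement studies compare
discretizations of one fixed continuum problem; with them the scheme shows
the expected ~4× L² error reduction per grid doubling.

## Estimation

The MLE problem is solved discretize-then-optimize: the PDE is reduced to
the fixed-grid ODE system and J becomes an ordinary function of θ.  The
kinetics are optimized as ξ = log₁₀ θ over the cube [−2, 1]⁵ — positivity
for free, comparable scales, and the same axis the profiles are plotted on.
By default the same grid generates and fits the data; a finer inference
grid can be configured to study discretization bias.

Multi-start local optimization: the box center plus seeded Latin-hypercube
starts drawn as a prefix of a fixed 64-point pool (so start sets are nested
and the best J is monotone in the number of starts).  Ties are broken
toward the optimum closest to the box center.  The default local method
("hybrid") is L-BFGS-B with finite differences (step 10⁻⁵ in log10 units,
deep correction memory `maxcor=20`) followed by a small-simplex Nelder–Mead
polish.  The deep memory and the polish are there for a structural reason:
the likelihood has a strongly correlated, gently curved valley through
(k₁, k₋₁, γ, α), and shallow-memory quasi-Newton line searches stall a few
tenths of a nat above its floor, which is enough to distort profile-based
intervals downstream.  Finite-difference steps are reliable here because
the integrator-induced non-smoothness of J is far below the step size
(point-to-point jitter ~10⁻⁶ nats at rtol 10⁻⁶).

## Profile likelihoods and identifiability

For each parameter the profile PL(θᵢ) re-optimizes all other kinetics at
stepped values of ξᵢ = log₁₀ θᵢ.  The walker starts at the MLE with step
0.02 (configurable), doubles the step while a step changes J by < 0.1 nats
and halves it when a step changes J by > 1 nat, and stops once the
likelihood ratio R = PL/L(θ̂) falls below `stop_margin` × the interval
threshold, or the box bound is reached.  The first crossing of the
threshold is localized by bisection until the bracketing −2 log R gap is
small, then the endpoint is interpolated linearly in −2 log R.

Confidence intervals collect {θᵢ : −2 log R(θᵢ) ≤ δ_α} with δ_α = χ²(α, 1)
(pointwise intervals, 1 degree of freedom); the default level is α = 98%,
giving δ ≈ 5.412 and a ratio cutoff exp(−δ/2) ≈ 0.0668.  An end that never
crosses before the box bound is flagged open; a parameter is practically
identifiable iff both ends cross.  If re-optimization ever finds a point
below the fit optimum, ratios are renormalized to the profile minimum and
the event is logged — the profile is also a global-optimality audit of the
fit.

Inner optimizations are warm-started from the previous profile point, with
the start extrapolated along the path of inner optima (they travel along
the correlation valley, and pure warm starts lag behind it).  Inner
convergence quality is the accuracy-critical knob of the whole analysis:
an under-converged inner problem overstates the profile J and therefore
*narrows* intervals.  The default is bound-constrained L-BFGS-B with the
same deep-memory settings as the outer fit; the cheaper small-simplex
option is retained for trend studies where only monotone comparisons
matter.

### Local (Hessian) approximation

For comparison, the Hessian of J at ξ̂ is taken by central second
differences (default step 0.02 log10 units) and inverted; the quadratic
model's profile along axis i has curvature 1/(H⁻¹)ᵢᵢ, giving asymptotic
intervals of half-width √(δ_α (H⁻¹)ᵢᵢ).  Because the likelihood valley is
curved, this quadratic picture is accurate only near the optimum; the
benchmark's degradation rate γ is the designed showcase — its Hessian
interval is finite and narrow while the true profile never crosses the
threshold below, i.e. the local approximation understates the uncertainty.
The finite-difference step is a genuine trade-off (too small measures
integrator bias wiggles, too large averages over the non-quadratic
valley); 0.02 ≈ the scale of the narrowest profile widths proved stable
across integrator tolerances.

## Synthetic-data generator

`generate_dataset` reproduces the benchmark scenario end-to-end: truth
θ = (0.5, 0.1, 5, 1, 0.1), y-source, five acquisition times t_k = k/5
(equally spaced in (0, 1]; spacing configurable), 50 pixels, σ = 10⁻²,
b = 10⁻⁴, and returns clean series, noisy series and the truth record.
Everything is deterministic given (parameters, seed, configuration).

What it emulates: pixel-integrated, offset-shifted, multiplicatively noisy
images of one stained species on a regular time base.  What it does not
emulate: point-spread functions, photobleaching, camera gain and shot-noise
mixtures, segmentation or registration artifacts, spatially varying
background, or a time-varying source.  Tests passing on these data
therefore validate the estimation and identifiability machinery, not
robustness to real-microscopy nuisance effects.

## Problem sizes used in tests and the acceptance script

The observation design (5 time points, 10×5 pixels, σ = 10⁻², b = 10⁻⁴,
truth parameters, bounds) is never scaled.  Simulation-heavy suites run on
a reduced grid — 10×10 for the seed ensembles of fits and profiles,
20×20 for single-fit unit checks — with integrator tolerances
rtol 10⁻⁶ / atol 10⁻⁸, and medians across a handful of seeds replace
large seed ensembles.  On coarse grids the rasterized vessel is effectively
wider than the continuum shape (at 10×10 the stem spans two cells ≈ 0.2
instead of 0.1), so coarse-grid runs are internally consistent experiments
(data and fit share the grid) but not grid-converged reproductions of the
50×50 scenario; the full-size configuration remains the library default.

## Known limitations

* Confidence-interval endpoints inherit the quality of the inner
  re-optimizations; the cheap inner settings can narrow intervals by tens
  of percent on strongly correlated parameters.  The strong defaults are
  calibrated against brute-force profile points, but there is no formal
  guarantee.
* The likelihood valley through (α, k₁, k₋₁, γ) is genuinely flat at this
  design's information content: interval widths for these parameters are
  sensitive to every modelling unknowable (exact source geometry, pixel
  arrangement, acquisition times).  Point estimates are much more stable
  than interval widths.
* Derivatives are finite-difference; no adjoint/sensitivity system is
  implemented.
* 2D only; no adaptive meshing; the three-species network is the only
  shipped model, though the solver/observation interfaces are written
  against generic fields.
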