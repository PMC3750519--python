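# rdprofile

Likelihood-based parameter estimation and practical-identifiability
analysis for 2D reaction–diffusion models observed as noisy, pixelated
image time series.

## The problem

Gradients of signaling molecules — such as the immobilized CCL21 gradients
that guide dendritic cells toward lymphatic vessels (haptotaxis) — can be
imaged by fluorescence microscopy as time series of 2D pixel images.
Fitting a mechanistic PDE model to such images is harder than fitting ODEs:
observations are pixel-area integrals of one species, intensities carry
multiplicative noise, and sparse/noisy data leave some kinetic parameters
poorly determined.  This package, aimed at modelers working with such
image data, provides the full chain:

1. a **forward model** — a three-species reaction–diffusion system on
   Ω = [0, 1]²: diffusing protein `p` released at rate α inside a
   vessel-shaped source Q, binding (k₁) to immobile substrate `s`,
   unbinding (k₋₁) from the complex `c`, degrading at rate γ,

       ∂ₜp = D Δp + α Q − k₁ p s + k₋₁ c − γ p
       ∂ₜs =            − k₁ p s + k₋₁ c
       ∂ₜc =              k₁ p s − k₋₁ c

   with no-flux boundaries, p(0)=c(0)=0, s(0)=s₀≡1;
2. an **observation model** y_{k,i} = b + ∫_{A_i} c(t_k, x) dx over M
   pixels at N acquisition times, plus multiplicative log-normal noise
   ȳ = ε y, log ε ~ N(0, σ²);
3. the **log-normal likelihood** and maximum-likelihood estimation of
   θ = (D, α, k₁, k₋₁, γ) ∈ [10⁻², 10¹]⁵ by multi-start bound-constrained
   optimization in log₁₀ θ (σ² is profiled analytically);
4. **profile likelihoods** PL(θᵢ) = max_{θ_j≠i} L(θ): likelihood-ratio
   confidence intervals {θᵢ : −2 log R(θᵢ) ≤ χ²(α, 1)}, practical
   identifiability verdicts (is the threshold crossed on both sides of the
   optimum within the box?), and the Hessian-based quadratic approximation
   for comparison — the local approximation famously understates the
   uncertainty of weakly informed parameters like γ;
5. a **synthetic-data generator** for the built-in benchmark scenario
   (y-shaped source, truth θ = (0.5, 0.1, 5, 1, 0.1), five time points in
   (0, 1], 50 pixels, σ = 10⁻², b = 10⁻⁴).

See `docs/methods.md` for the numerical choices and their rationale.

## Worked example

```python
import rdprofile as rd

# benchmark dataset on a reduced 20x20 grid (fast); 50x50 is the default
ds = rd.generate_dataset(seed=1, grid=rd.DomainGrid(nx=20), rtol=1e-6, atol=1e-8)
ctx = rd.ModelContext(grid=ds.grid, source=ds.source, rtol=1e-6, atol=1e-8)

fit = rd.fit_mle(ds.noisy, ctx, n_starts=2, seed=0, max_iter=100)
print(fit.theta_hat.kinetics)     # MLE for (D, alpha, k1, km1, gamma)

prof = rd.profile_parameter("gamma", fit, ds.noisy, ctx,
                            options=rd.ProfileOptions(alpha=0.98))
print(prof.ci.lower_open, prof.ci.upper, prof.verdict)
```

Running `python examples/02_fit_parameters.py` prints (seed 1, 20×20 grid):

```
param     truth   estimate  rel.err
D         0.500     0.5099    +2.0%
alpha     0.100     0.1020    +2.0%
k1        5.000     4.8586    -2.8%
km1       1.000     0.9550    -4.5%
gamma     0.100     0.2059   +105.9%
```

D, α, k₁, k₋₁ land within a few percent of the truth; γ lands far away at
nearly the same likelihood — the data barely constrain degradation on this
time horizon.  `examples/03_profile_identifiability.py` makes that precise:
the γ profile never crosses the 98% threshold toward small values (open
lower end, "practically non-identifiable"), while the other four parameters
get closed intervals; the Hessian interval for γ is much narrower than the
profile interval, i.e. the quadratic approximation understates the real
uncertainty.

The same pipeline is scriptable from the shell:

```bash
rdprofile simulate --out data/ --seed 1
rdprofile fit --config cfg.yaml --data data/noisy.npz --out fit.json
rdprofile profile --config cfg.yaml --data data/noisy.npz --param all --out prof/
rdprofile run --config cfg.yaml --out results/
```

## Layout

| path | contents |
| --- | --- |
| `src/rdprofile/model.py` | parameters, reaction–diffusion RHS, BDF forward solver |
| `src/rdprofile/sources.py`, `grid.py` | vessel geometry, cell-centered grid |
| `src/rdprofile/observation.py` | pixel layouts, area-integral observation map |
| `src/rdprofile/synthetic.py` | benchmark dataset generator, log-normal noise |
| `src/rdprofile/likelihood.py` | log-normal NLL, analytic σ² profile |
| `src/rdprofile/estimation.py` | multi-start MLE in log₁₀ parameters |
| `src/rdprofile/profiling.py` | profile walker, CIs, verdicts, Hessian comparison |
| `src/rdprofile/io.py`, `config.py`, `pipeline.py`, `cli.py` | artifacts, YAML config, end-to-end pipeline, CLI |
| `examples/` | narrative scripts, one per capability |
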