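"""Maximum-likelihood fit of the five kinetic parameters.

Generates a noisy dataset on a reduced grid (for a quick run), then
minimizes the negative log-likelihood over log10-parameters in the box
[10^-2, 10]^5, profiling the noise variance analytically.
"""

import numpy as np

import rdprofile as rd

dataset = rd.generate_dataset(seed=1, grid=rd.DomainGrid(nx=20),
                              rtol=1e-6, atol=1e-8)
ctx = rd.ModelContext(grid=dataset.grid, source=dataset.source,
                      rtol=1e-6, atol=1e-8)

fit = rd.fit_mle(dataset.noisy, ctx, n_starts=2, seed=0, max_iter=100)

print(f"{'param':6s} {'truth':>8s} {'estimate':>10s} {'rel.err':>8s}")
for name, true, est in zip(rd.KINETIC_NAMES, dataset.truth.kinetics,
                           fit.theta_hat.kinetics):
    print(f"{name:6s} {true:8.3f} {est:10.4f} {est / true - 1:+8.1%}")
print(f"\nJ(theta*) = {fit.nll_opt:.3f} nats over {dataset.noisy.values.size} "
      f"observations; sigma2_hat = {fit.sigma2_hat:.3e} (generating value 1e-4)")
print(f"{fit.n_converged}/{len(fit.starts)} starts converged")
print("\nExpect D, alpha, k1, km1 within a few percent of truth; gamma is "
      "weakly informed by this design and can land far from 0.1 at almost "
      "the same likelihood.")
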