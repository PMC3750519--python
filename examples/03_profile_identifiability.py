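"""Profile-likelihood identifiability analysis.

Profiles each kinetic parameter (re-optimizing the others at stepped
values), locates the 98% likelihood-ratio confidence interval, classifies
practical identifiability, and contrasts the intervals with the Hessian
(quadratic) approximation — which famously understates the uncertainty of
the degradation rate gamma.

Runs on a coarse 10x10 grid; expect several minutes.
"""

import rdprofile as rd

dataset = rd.generate_dataset(seed=1, grid=rd.DomainGrid(nx=10),
                              rtol=1e-6, atol=1e-8)
ctx = rd.ModelContext(grid=dataset.grid, source=dataset.source,
                      rtol=1e-6, atol=1e-8)
fit = rd.fit_mle(dataset.noisy, ctx, n_starts=1, seed=0, max_iter=100)
options = rd.ProfileOptions(alpha=0.98, init_step=0.08, inner_max_iter=30,
                            inner_tol=3e-6, stop_margin=0.5)
local = rd.local_approximation(fit, dataset.noisy, ctx, alpha=0.98)

print(f"threshold: delta = chi2(0.98, 1) = {rd.delta_alpha(0.98):.3f}, "
      f"ratio cutoff exp(-delta/2) = {rd.ratio_threshold(0.98):.4f}\n")
print(f"{'param':6s} {'mle':>8s} {'98% profile CI':>22s} {'hessian CI':>22s}  verdict")
for i, name in enumerate(rd.KINETIC_NAMES):
    prof = rd.profile_parameter(name, fit, dataset.noisy, ctx, options=options)
    ci = prof.ci
    lo = ("<" if ci.lower_open else "") + f"{ci.lower:.4f}"
    hi = (">" if ci.upper_open else "") + f"{ci.upper:.4f}"
    hlo, hhi = local.ci[i]
    print(f"{name:6s} {10**prof.xi_hat:8.4f} {f'[{lo}, {hi}]':>22s} "
          f"{f'[{hlo:.4f}, {hhi:.4f}]':>22s}  {prof.verdict}")

print("\nA '<' marks an open end: the likelihood ratio never drops below the "
      "cutoff before the box bound, so the data place no lower bound on that "
      "parameter (practical non-identifiability). For gamma the Hessian "
      "interval is much narrower than the profile interval — the quadratic "
      "approximation understates the true uncertainty.")
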