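"""Cross-validating the exact solver with Monte Carlo simulation.

Runs 100 000 replicate trajectories of the joint chain at N = 20 and checks
that the exact fixation probability and conditional time fall inside the
simulator's 99% confidence intervals.
"""

from coculture import (
    CompositionState,
    LanguageModelParams,
    build_language_model,
    estimate_fixation,
    solve_model,
)

params = LanguageModelParams(N=20, phi=0.1, eta=0.5)
model = build_language_model(params)

res = solve_model(model, units="steps")
est = estimate_fixation(
    model, CompositionState(1, "+"), n_runs=100_000, seed=7, units="steps"
)

print(f"N = {params.N}, phi = {params.phi}, eta = {params.eta}")
print(f"solver:    epsilon = {res.epsilon[1, 0]:.5f}, "
      f"t = {res.t_conditional[1, 0]:.1f} steps")
print(f"simulator: p_hat   = {est.p_hat:.5f}  99% CI "
      f"[{est.p_ci[0]:.5f}, {est.p_ci[1]:.5f}]")
print(f"           t_hat   = {est.t_hat:.1f}  99% CI "
      f"[{est.t_ci[0]:.1f}, {est.t_ci[1]:.1f}]  ({est.n_fixed} fixed runs)")
print()
in_p = est.p_ci[0] <= res.epsilon[1, 0] <= est.p_ci[1]
in_t = est.t_ci[0] <= res.t_conditional[1, 0] <= est.t_ci[1]
print(f"solver inside simulation intervals: probability={in_p}, time={in_t}")
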