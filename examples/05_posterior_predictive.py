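"""Posterior predictive check with the pluripotency statistic.

After a (short) ABC-SMC run, datasets simulated from posterior draws
should reproduce the reference's fate split.  The test statistic is
S(X) = log(p / (1 - p)) with p the fraction of cells in the high-Nanog
K-means cluster at the final time.
"""

import fatescape as fs

reference = fs.generate_reference(n_cells=100, T=10, seed=21)
simulate, distance, prior = fs.make_grn_problem(reference, metric="sinkhorn")

populations = fs.abc_smc(simulate, distance, prior, epsilon_target=0.0,
                         N=40, max_sims=1500, seed=21)
final = populations[-1]
print(f"ran {len(populations)} generations, final eps = {final.tolerance:.3f}")

res = fs.posterior_predictive_check(
    final, reference, n_draws=40, seed=21, prior=prior
)
print(f"\nS(reference)            = {res.S_reference:+.3f}")
print(f"posterior draws: mean S = {res.S_posterior_draws.mean():+.3f}")
print(f"tail probability Pr(S(X) > S(D)) = {res.tail_prob:.2f}")
print(f"mean squared error around S(D)   = {res.mse:.3f}")
# A tail probability away from 0 and 1 means the reference looks like
# a typical draw from the fitted model; the MSE quantifies how tightly
# the posterior pins the fate split.
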