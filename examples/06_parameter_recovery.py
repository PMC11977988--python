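"""Small parameter-recovery study: bias and CI coverage of the estimator.

Replicates panels at a published panel size with a known rate ratio, fits
each, and summarises the mean recovered RR and 95% CI coverage.  (The
acceptance script runs the same design at 200 replicates per target.)
"""

import numpy as np

from watchdrift import ModelSpec, fit_nb_glmm, simulate_panel

rng = np.random.default_rng(123)
true_rr, n_participants, n_rep = 1.13, 166, 40

rrs, covered = [], 0
for _ in range(n_rep):
    panel = simulate_panel(n_participants, true_rr=true_rr, rng=rng)
    res = fit_nb_glmm(panel, ModelSpec())
    rrs.append(res.rate_ratio)
    covered += int(res.ci_low <= true_rr <= res.ci_high)

print(f"true RR {true_rr:.2f}, {n_rep} replicates of {n_participants} participants x 14 days")
print(f"mean recovered RR: {np.mean(rrs):.4f}  (bias {100 * (np.mean(rrs) / true_rr - 1):+.2f}%)")
print(f"SD of estimates:   {np.std(rrs):.4f}")
print(f"95% CI coverage:   {covered}/{n_rep}")
print("\nAn unbiased estimator with honest intervals shows ~0% bias and ~95% coverage.")
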