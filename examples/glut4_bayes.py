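"""Bayesian inference for GLUT4 translocation under biased timing error.

The insulin dose lands up to Delta minutes after the protocol time
(U ~ U(0, Delta)), while the likelihood naively assumes protocol timing.
With little response heterogeneity (small sigma_Y) the posterior is so
tight that the credibility interval misses the true rate; more
heterogeneity widens the interval until it covers the truth again.
"""

import numpy as np

from mistime import generate_glut4_dataset
from mistime.models import Glut4Params
from mistime.smc_bayes import Glut4LogLik, default_glut4_priors, posterior_metrics, run_smc

truth = Glut4Params(P0=0.1, k=0.1, M=1.0)
Delta = 1.0  # minutes of (always positive) dosing delay

print(f"true parameters: P0={truth.P0}, k={truth.k}/min, M={truth.M}; Delta={Delta} min\n")
print(f"{'sigma_Y':>8s} {'MAP k':>8s} {'95% CI for k':>22s} {'distance to truth':>18s}")
for sigma_Y in (0.02, 0.05, 0.1, 0.2):
    ss = np.random.SeedSequence(0).spawn(2)
    ds = generate_glut4_dataset(truth, Delta=Delta, sigma_Y=sigma_Y, n_rep=1000,
                                rng=np.random.default_rng(ss[0]))
    particles = run_smc(Glut4LogLik(ds, sigma_Y), default_glut4_priors(),
                        n_particles=1000, rng=np.random.default_rng(ss[1]))
    pm = posterior_metrics(particles, {"P0": truth.P0, "k": truth.k, "M": truth.M})
    lo, hi = pm.ci["k"]
    print(f"{sigma_Y:8.2f} {pm.map_estimate['k']:8.4f} [{lo:9.4f}, {hi:9.4f}] {pm.ci_distance['k']:18.5f}")

print(
    "\nA zero distance means the interval contains k = 0.1.  Heterogeneity "
    "(larger sigma_Y) buys tolerance to the timing error."
)
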