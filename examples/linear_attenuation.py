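"""Classical timing error attenuates a linear slope; Berkson error does not.

Generates one dataset per linear design, fits the line to the true and to
the observed (error-contaminated) independent values, and compares against
the reliability-ratio prediction lambda = sigma_x^2/(sigma_x^2+sigma_u^2).
"""

import numpy as np

from mistime import fit_least_squares, generate_linear_dataset
from mistime.corrections import reliability_ratio

rng = np.random.default_rng(42)

lam = reliability_ratio(sigma_x2=1.0, sigma_u2=0.25)
print(f"reliability ratio lambda = {lam:.3f} -> naive slope concentrates at {lam:.3f}\n")

for design in ("noncontrolled_classical", "noncontrolled_berkson", "controlled_berkson"):
    ds = generate_linear_dataset(design, rng=rng)
    true_fit = fit_least_squares("linear", ds, time_column="true")
    naive_fit = fit_least_squares("linear", ds, time_column="protocol")
    print(f"{design}:")
    print(f"  true-data slope  = {true_fit.theta_hat['beta_x']:.4f}  (R2 {true_fit.r2:.4f})")
    print(f"  observed slope   = {naive_fit.theta_hat['beta_x']:.4f}  (R2 {naive_fit.r2:.4f})")

print(
    "\nOnly the non-controlled classical design shows the systematic shrinkage "
    "towards lambda*beta_x; Berkson designs stay centred at the true slope 1."
)
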