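"""Fit the penalized NB dose-response model and read off the survival curve.

Counts are modelled as negative binomial with a log link; each strain gets
its own penalized spline of sqrt(dose), and the unknown inoculum size is
absorbed by the intercept and per-experiment effects.  Survival fractions
are ratios of predicted means, so they need no knowledge of the inoculum.
"""

import numpy as np

import lethaldose as ld

ds = ld.simulate_dataset(ld.default_config(seed=42))
fit = ld.fit_penalized_nb(ds)

print(f"converged: {fit.converged}, dispersion theta = {fit.theta:.2f}")
for s in fit.strains:
    print(f"{s}: lambda = {fit.lambdas[s]:.3g}, edf = {fit.edf[s]:.2f}")

doses = np.array([0.0, 1.0, 5.0, 10.0, 20.0])
print("\nmodel-based survival fractions:")
print("dose   " + "  ".join(f"{s:>8s}" for s in fit.strains))
for d in doses:
    fracs = [ld.survival_curve(fit, s, [d])[0] for s in fit.strains]
    print(f"{d:5.0f} " + "  ".join(f"{f:8.4f}" for f in fracs))
# A fraction of 0.5 at dose d means the model predicts half the unexposed
# population would be recovered after exposure d; the dose where each
# column crosses 0.5 is that strain's LD50.
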