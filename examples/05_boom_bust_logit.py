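"""Boom/bust logistic models: endogenous lag vs exogenous climate.

Generates labels from a known logistic law on three inputs and fits the
three model variants: 1V (lagged growth only), 2V (stability + solar),
and 3V (all three).  Prints coefficient recovery and the hindcast's
phase overlap with the generating signal.
"""

import numpy as np
from scipy.special import expit

from paleocycles import (GridSeries, fit_boom_bust_logit, phase_overlap,
                         predict_boom_minus_bust)

rng = np.random.default_rng(7)
N = 500
TRUE = {"intercept": 0.0, "lagged_rgr": 0.5, "stability": 1.3, "tsi": 1.0}


def smooth(n, m=12):
    v = np.convolve(rng.standard_normal(n + m), np.ones(m) / m,
                    mode="same")[:n]
    return (v - v.mean()) / v.std()


x = {name: smooth(N) for name in ("lagged_rgr", "stability", "tsi")}
eta = TRUE["intercept"] + sum(TRUE[k] * x[k] for k in x)
y = (rng.uniform(size=N) < expit(eta)).astype(float)

inputs = {k: GridSeries(12000.0, 100.0, v) for k, v in x.items()}
labels = GridSeries(12000.0, 100.0, y)

models = {}
for variant in ("1V", "2V", "3V"):
    model = fit_boom_bust_logit(variant, inputs, labels)
    models[variant] = model
    print(f"{variant}: log-likelihood {model.llf:9.2f}, "
          f"n = {model.n_obs}, ridge fallback = {model.ridge}")

print("\n3V coefficient recovery (estimate +/- SE vs truth):")
names = ("intercept",) + models["3V"].input_names
for name, est, se in zip(names, models["3V"].params, models["3V"].bse):
    print(f"  {name:10s} {est:+.3f} +/- {se:.3f}   (true {TRUE[name]:+.2f})")

hindcast = predict_boom_minus_bust(models["3V"], inputs)
generating = GridSeries(12000.0, 100.0, eta)
print(f"\n3V hindcast (2p-1) phase overlap with the generating signal: "
      f"{phase_overlap(generating, hindcast):.1f}%")
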