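"""Synchrony statistics between two preprocessed series.

Shows the three comparative statistics on controlled cases: a series
against itself (perfect synchrony), against its negation (perfect
antiphase), and against independent noise (the ~50% baseline).
"""

import numpy as np

from paleocycles import (GridSeries, classify_synchrony, compare,
                         phase_overlap, preprocess)

rng = np.random.default_rng(42)


def noise():
    return preprocess(GridSeries(14900.0, 100.0, rng.standard_normal(120)))


x = noise()
negated = GridSeries(x.t0, x.step, -x.values)

for name, other in (("itself", x), ("its negation", negated),
                    ("independent noise", noise())):
    result = compare(x, other)
    print(f"x vs {name:18s}: overlap = {result.overlap:6.2f}%, "
          f"r_T = {result.r_t:+.3f}, label = {result.label}")

overlaps = [phase_overlap(noise(), noise()) for _ in range(200)]
print(f"\nMonte-Carlo baseline over 200 independent pairs: "
      f"{np.mean(overlaps):.2f}% (sd {np.std(overlaps):.2f})")
print("classification thresholds: strong synchrony above 67% overlap; "
      "antiphase below 49% with negative r_T:",
      classify_synchrony(70.0, 0.5), "/", classify_synchrony(45.0, -0.2))
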