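"""Evaluate the double-logistic decline curve.

The expected 5-year TFR decrement g(theta, f) is the sum of two logistic
curves in the current TFR level f: it vanishes near the onset level
U = sum(Delta) and below the end-of-transition level Delta_4, and peaks
mid-transition at up to d_max children per 5 years.
"""

import numpy as np

import ferticast as fc

theta = fc.DeclineParams(delta=(2.0, 1.0, 1.0, 2.0), d_max=1.0)
print(f"onset level U = {theta.onset_level} children, max pace d = {theta.d_max}")
for f in np.arange(0.5, 7.0, 0.5):
    g = fc.double_logistic(theta, float(f))
    bar = "#" * int(40 * max(g, 0) / theta.d_max)
    print(f"  f = {f:4.1f}  g = {g:+.4f}  {bar}")
print("The decrement is applied as f_next = f - g(theta, f) + noise while a "
      "region is in its fertility transition (and is 0 for f <= 1).")
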