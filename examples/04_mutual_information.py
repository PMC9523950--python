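"""Contrast information in neural responses, with bias correction.

Shows the limited-sampling problem and its Panzeri-Treves correction on
synthetic stimulus/response data, then a significance map with the
bootstrap shuffle test.
"""

import numpy as np

from fhmnet import bootstrap_significance, mi_corrected
from fhmnet.synth import generate_mi_dataset

# independent responses: plug-in MI is biased upward, the correction fixes it
s, r = generate_mi_dataset(50, "none", seed=1)
est = mi_corrected(s, r)
print(f"independent data (n={s.size}):  plug-in {est.mi:.3f} bits, "
      f"corrected {est.mi_corrected:+.3f} bits")

# contrast-dependent responses
s, r = generate_mi_dataset(50, "planted", seed=2, snr=1.0)
est = mi_corrected(s, r)
print(f"planted dependence:            plug-in {est.mi:.3f} bits, "
      f"corrected {est.mi_corrected:.3f} bits")

# a 5-element response map where only the first element is informative
rng = np.random.default_rng(3)
maps = np.column_stack([r] + [rng.standard_normal(r.size) for _ in range(4)])
out = bootstrap_significance(s, maps, n_iter=500, seed=4)
print("significance (Bonferroni over 5 map elements):",
      [e.significant for e in out])

print()
print("The plug-in estimator reports spurious information on independent")
print("data; the Panzeri-Treves correction centres it at zero, and the")
print("shuffle test flags only the genuinely informative map element.")
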