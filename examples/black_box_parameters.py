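"""Dynamic parameters straight from a labeling curve, no model assumed.

Builds two noise-free wash-out curves — a single pool and a two-pool
mixture — and prints the age-based parameters the curve geometry encodes:
mean age (area under the curve), half-life (crossing of 1/2), expected
decay rate (initial slope), and mean residence time.
"""

import numpy as np

from agekin import LabelingCurve, summary_parameters

t = np.linspace(0.0, 2000.0, 401)   # minutes

curves = {
    "single pool (rate 0.01/min)": np.exp(-0.01 * t),
    "mixture 0.5@0.02 + 0.5@0.004": 0.5 * np.exp(-0.02 * t) + 0.5 * np.exp(-0.004 * t),
}

for name, values in curves.items():
    p = summary_parameters(LabelingCurve(name, t, values), noise_sd=1e-6)
    print(f"{name}")
    print(f"  mean age        {p.mean_age:8.1f} min   (AUC of the curve)")
    print(f"  half-life       {p.half_life:8.1f} min   (median metabolic age)")
    print(f"  decay rate      {p.expected_decay_rate:8.4f} /min  (-f'(0))")
    print(f"  residence time  {p.mean_residence_time:8.1f} min   (-1/f'(0))")
    print(f"  mean RTL        {p.mean_rtl:8.1f} min   (= 2 x mean age here)")

print("\nNote: for the mixture, the mean residence time (83.8 min) is far"
      "\nbelow the mean age (150 min) — short-lived molecules dominate the"
      "\nexits, long-lived ones dominate the standing pool.")
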