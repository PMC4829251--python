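"""How single-parameter changes reshape AF progression.

Reruns the four-way comparison — baseline, age-related activation
plateau A1 reduced tenfold, episode-remodelling ceiling Amax reduced
tenfold, and recovery decay rate lambda reduced by a third — with 100
sample paths each, and prints the burden-saturation age and the episode
durations observed over a 60-65 yr monitoring window.
"""

import numpy as np

from afprog import variant_comparison

for s in variant_comparison(n=100, master_seed=3):
    b = s.burden_by_age
    over = b.t_grid[b.mean > 0.99]
    sat = f"age {over[0] + 1:.0f}" if len(over) else "never (within horizon)"
    mids = np.sqrt(s.duration_bins[:-1] * s.duration_bins[1:])
    cum = np.cumsum(s.duration_hist)
    med = mids[np.searchsorted(cum, cum[-1] / 2)] * 365 * 24 * 60
    print(f"{s.label:10s} burden reaches 1 : {sat:24s} "
          f"final burden {b.mean[-1]:.3f}  "
          f"median episode 60-65 yr: {med:8.1f} min")
# Reducing A1 or Amax delays progression but burden still saturates at 1;
# slowing the recovery decay (lambda) keeps recovery high enough that not
# every patient reaches permanent AF and episodes stay an order of
# magnitude shorter.
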