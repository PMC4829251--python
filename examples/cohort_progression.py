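"""Population statistics of AF progression from an ensemble of patients.

Runs 200 independent patients (per-patient random streams spawned from
one master seed), then prints the onset-age distribution and the
onset-aligned progression curves: mean annual burden and episodes per
year as functions of time since each patient's own paroxysmal onset.
"""

import numpy as np

from afprog import baseline_parameters, run_ensemble

summary = run_ensemble(baseline_parameters(), n=200, master_seed=7)

onsets = summary.onset_frame()
print(f"n = {summary.n} patients")
print(f"mean (sd) paroxysmal onset : {onsets.paroxysmal_onset_yr.mean():.1f} "
      f"({onsets.paroxysmal_onset_yr.std():.1f}) yr")
print(f"mean (sd) permanent onset  : {onsets.permanent_onset_yr.mean():.1f} "
      f"({onsets.permanent_onset_yr.std():.1f}) yr")
interval = onsets.permanent_onset_yr - onsets.paroxysmal_onset_yr
print(f"mean paroxysmal->permanent : {interval.mean():.1f} yr")

c = summary.counts_after_paroxysmal
peak = int(np.argmax(c.mean))
print(f"episodes/yr peak           : {c.mean[peak]:.0f} episodes at "
      f"{c.t_grid[peak]:.0f}-{c.t_grid[peak] + 1:.0f} yr after onset")
# episode frequency rises after onset, peaks roughly two decades later,
# then falls as episodes merge into ever-longer (finally permanent) AF.

b = summary.burden_by_age
sat = b.t_grid[b.mean > 0.99]
print(f"mean annual burden > 0.99 from age {sat[0] + 1:.0f}")
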