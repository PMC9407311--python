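"""Free-running rhythmicity and period estimation in constant darkness.

Simulates short- (tau=23.5 h) and normal-period (tau=24 h) cohorts over 8
DD days, computes chi-square periodograms on DD days 2-7 (30-min bins,
candidate periods 16-32 h), and summarizes percent rhythmic and the mean
free-running period per genotype.
"""

import dataclasses

from clockscreen import (
    PRESETS,
    chi2_periodogram,
    estimate_period,
    group_rhythmicity,
    select_days,
    simulate_fly_activity,
)

for name, tau in [("wild-type", 24.0), ("short-period", 23.5)]:
    preset = dataclasses.replace(PRESETS["control"], tau_hours=tau)
    calls = []
    for s in range(16):
        fs = simulate_fly_activity(preset, 0, 8, seed=400 + s,
                                   fly_id=f"{name}-{s}")
        pg = chi2_periodogram(select_days(fs, "dd_rhythm"))
        calls.append(estimate_period(pg))
    summary = group_rhythmicity(calls, genotype=name)
    print(f"{name:>13}: {summary['percent_rhythmic']:.0f}% rhythmic, "
          f"period {summary['mean_period_h']:.2f} +/- "
          f"{summary['sem_period_h']:.2f} h (n={summary['n']})")
# Each cohort is called rhythmic and its mean period matches the
# programmed clock speed to within the 0.5-h candidate-period step.
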