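"""Generate a synthetic monitoring study and summarize the effort.

The generator emulates a two-year coastal-lagoon deployment campaign:
21 short moorings, a mixed semidiurnal tide, the synodic moon cycle, a
seasonal SST curve, and hourly dp10m counts (detection-positive 10-min
intervals per hour, 0–6) drawn from a Poisson model with known smooth
effects.
"""

import whistlegam as wg

schedule, forcings, truth, records = wg.simulate_study(seed=1)

s = wg.summarize_effort(records)
print(f"deployments:        {len(schedule)}")
print(f"monitored hours:    {s.total_hours}")
print(f"positive hours:     {s.positive_hours}  (hours with >=1 detected whistle)")
print(f"10-min intervals:   {s.total_bins}, of which {s.positive_bins} detection-positive")
print(f"mean dp10m per h:   {s.positive_bins / s.total_hours:.2f}")
print()
print("per-deployment breakdown (first 5):")
print(s.per_deployment.head().to_string(index=False))
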