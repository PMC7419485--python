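"""Generate a synthetic dyad cohort that mirrors the emulated study design.

Thirty mother-infant dyads (15 boys, 15 girls), two 5-minute coded play
sessions per month over months 3-12 of age, 26 behavior codes. The
session-level log carries both encodings (seconds of each behavior, and
number of occurrences); pooling by month gives 10 equally spaced rows
per dyad.
"""

import dyadvar as dv

config = dv.GeneratorConfig(seed=42)
events = dv.generate_events(config)
panel = dv.aggregate_monthly(events, "duration_seconds")

print(f"event rows:            {len(events)}")
print(f"dyads:                 {panel.n_dyads} "
      f"({sum(g == 'boy' for g in panel.groups)} boys, "
      f"{sum(g == 'girl' for g in panel.groups)} girls)")
print(f"sessions per infant:   {events.groupby('dyad_id').apply(lambda d: d.groupby(['month', 'session']).ngroups, include_groups=False).iloc[0]}")
print(f"monthly rows per dyad: {panel.n_months} (months {panel.months[0]}-{panel.months[-1]})")
print(f"behavior codes:        {panel.m}")

# Each dyad-month cell is the total seconds (or count) of one behavior,
# summed over that month's two sessions; a 30 x 10 x 26 array feeds the VAR.
print(f"panel array shape:     {panel.values.shape}")
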