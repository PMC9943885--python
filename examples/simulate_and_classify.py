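"""Simulate a full competitive-exclusion scenario and classify its zones.

The default scenario spans 136 years: a single competitor appears in year
60 and adds upward drift to the trait frontier, the frontier strikes the
fixed upper wall near year 90, and from year 100 the lower feasible bound
rises, truncating the trait distribution's lower tail. The pipeline sees
only the design-level records and the event table; the printout compares
what it detects against the generator's bookkeeping.
"""

from traitwalls import ScenarioConfig, analyze_scenario

truth, result = analyze_scenario(ScenarioConfig(seed=3))

print("detected phases (yearly-mean changepoints):")
for p in result.phases:
    print(f"  {p.start_year:>3}-{p.end_year:<3}  slope {p.slope:+.3f} "
          f"[{p.slope_ci_low:+.3f}, {p.slope_ci_high:+.3f}]")

print("\nbest-supported evolutionary mode per phase:")
for idx, start, end, fits in result.fit_table.frames:
    best = fits[0]
    print(f"  {start:>3}-{end:<3}  {best.model:<12} (Akaike weight {best.akaike_weight:.3f})")

z = result.zones
print("\nzone classification:")
for zone in z.zones:
    print(f"  {zone.zone:<10} {zone.start_year}-{zone.end_year}")
print(f"\ndirectional shift detected: year {z.directional_shift_year} "
      f"(competitor truly appeared in year 60)")
print(f"right-wall collision:       year {z.right_wall_year} "
      f"(frontier truly first struck the wall in year {truth.wall_contact_year})")
print(f"left-wall detachment:       year {z.left_wall_detach_year} "
      f"(exclusion truly began in year {truth.detachment_year})")
print("\nThe danger zone opens where the yearly mean switches from an "
      "unbiased to a directional random walk beside a competitor event; "
      "the extinction zone opens where the yearly minimum starts rising "
      "significantly — no population remains shielded from competition.")
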