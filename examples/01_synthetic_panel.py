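"""Generate a synthetic regional TFR panel with known ground truth.

Each region draws its transition parameters from the national hierarchy,
declines from a high-fertility plateau and, once its transition completes,
oscillates around replacement level.  The recorded truth lets every later
stage be checked against known values.
"""

import ferticast as fc

spec = fc.SyntheticSpec(n_regions=5, seed=42)
panel, truth = fc.generate_panel(spec)

print(f"panel: {len(panel)} regions x {len(panel.grid)} periods "
      f"({panel.grid.labels[0]} .. {panel.grid.labels[-1]})")
for s in panel.series:
    rt = truth.regions[s.region_id]
    lam = rt.lam if rt.lam is not None else "-"
    print(f"  {s.region_id}: onset U={rt.U:.2f} children at period {rt.tau}, "
          f"max pace d={rt.theta.d_max:.2f}/5yr, post-transition from period {lam}")
print("first region's TFR path:", ", ".join(f"{v:.2f}" for v in panel.series[0].values))
print("Each path starts near its onset level U, falls by up to d children per "
      "5-year period mid-transition, and levels off (or recovers) below 2.")
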