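"""Pulse-chase quantification of per-pole growth in two strains.

Pre-existing cell wall is labeled at time zero; material inserted at the
poles afterwards is dark. Measuring the dark margins of each cell's axial
profile at birth and just before division gives the growth contributed by
each pole over one generation.
"""

import numpy as np

import polegrowth as pg

strains = {
    "WT": dict(rate_old=0.14, rate_new=0.06),     # 70% old-pole growth
    "dlamA": dict(rate_old=0.10, rate_new=0.10),  # symmetric growth
}

for name, rates in strains.items():
    config = pg.SimulationConfig(noise_sd=5.0, seed=3, **rates)
    measurements = []
    for rec in pg.simulate_cohort(config, 50):
        birth, pre = pg.render_pulse_chase_pair(rec, config)
        measurements.append(pg.measure_polar_growth(birth, pre, threshold_fraction=0.5))
    old = np.median([m.growth_old_um for m in measurements])
    new = np.median([m.growth_new_um for m in measurements])
    share = np.median([m.old_pole_share for m in measurements])
    asym = pg.AsymmetrySummary.from_measurements(measurements)
    truth = rates["rate_old"] / (rates["rate_old"] + rates["rate_new"])
    print(f"{name:>6}: median growth old pole {old:.2f} um, new pole {new:.2f} um; "
          f"old-pole share {share:.2f} (truth {truth:.2f}); "
          f"asymmetry index {asym.median:+.2f}")

print("\nthe measured shares recover the configured asymmetry: the mutant-like")
print("strain grows equally from both poles, the wild type mostly from the old pole.")
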