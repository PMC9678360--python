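"""Average kymograph of an old-pole protein with late septal relocalization.

25 simulated cells are followed from birth to division; each cell's axial
fluorescence profiles are mapped onto a common (relative cycle time x
relative length) grid and averaged. With per-cell row normalization the
result reads as the probability of finding the protein at a given position
at a given cycle stage.
"""

import numpy as np

import polegrowth as pg

config = pg.SimulationConfig(
    localization_mode="old_pole",
    septal_onset_fraction=0.75,   # septal relocalization starts at 75% of the cycle
    septal_transfer_fraction=0.5,  # half the polar signal moves to the septum
    noise_sd=5.0,                  # 5% of the spot amplitude
    seed=2,
)

cohort = pg.simulate_cohort(config, 25)
kymos = [
    pg.grid_normalize_track(pg.render_localization_track(rec, config), T=50, L=100)
    for rec in cohort
]
avg = pg.average_kymographs(kymos, normalization="row_sum")

taus = np.linspace(0, 1, avg.values.shape[0])
L = avg.values.shape[1]
for tau_probe in (0.1, 0.5, 0.9):
    row = avg.values[np.argmin(np.abs(taus - tau_probe))]
    mid = row[int(0.4 * L) : int(0.6 * L)]
    # a real septal peak stands well above noise: ask for 10% of the row max
    septal = mid.max() > 0.1 * row.max()
    print(f"cycle fraction {tau_probe:.1f}: global peak at relative position "
          f"{row.argmax() / (L - 1):.2f} (0 = new pole, 1 = old pole); "
          f"mid-cell septal peak: {'yes' if septal else 'no'}")

print("\nthe signal sits at the old pole throughout; after the septal onset")
print("(cycle fraction 0.75) a second, smaller peak appears near mid-cell --")
print("the future new poles of the daughter cells.")
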