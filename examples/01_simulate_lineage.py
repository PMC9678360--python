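"""Simulate a lineage of polar-growing cells and inspect its ground truth.

Cells elongate at both poles — more at the established "old" pole than at
the "new" pole formed at the last division — and divide on reaching a
length threshold. Every cell records how much each pole grew, which is the
ground truth all downstream measurements are validated against.
"""

import numpy as np

import polegrowth as pg

# wild-type-like asymmetry: 70% of elongation at the old pole
config = pg.SimulationConfig(
    rate_old=0.14,   # um/frame (one frame = 15 min)
    rate_new=0.06,
    birth_length=2.5,
    division_length=5.0,
    n_founders=3,
    n_generations=3,
    seed=1,
)

records = pg.simulate_lineage(config)
non_founders = [r for r in records if r.mother_id is not None]

print(f"simulated {len(records)} cells ({len(non_founders)} with known pole identity)")
print(f"{'cell':>4} {'mother':>6} {'born':>5} {'divides':>7} "
      f"{'pole age':>8} {'old-pole share':>14}")
for r in records[:8]:
    div = r.division_frame if r.division_frame is not None else "-"
    print(f"{r.cell_id:>4} {str(r.mother_id):>6} {r.birth_frame:>5} {str(div):>7} "
          f"{r.old_pole_age_generations:>8} {r.truth_old_pole_share:>14.3f}")

shares = [r.truth_old_pole_share for r in non_founders]
print(f"\nmedian old-pole share of elongation: {np.median(shares):.3f}")
print("(the configured split is 0.14/0.20 = 0.70; per-cell jitter moves "
      "individual cells around it)")
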