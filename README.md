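# polegrowth

Single-cell image-analysis toolkit for **asymmetric polar growth in
mycobacteria** — for microbiologists quantifying where rod-shaped,
polar-growing cells put new cell wall and where their proteins localize
over the cell cycle.

Mycobacteria elongate from their poles, not their side walls, and the two
poles are unequal: the established **old pole** (inherited from an earlier
generation) normally grows faster than the **new pole** formed at the last
division. `polegrowth` implements the computational side of that biology:

- **Lineage-aware pole identity** — the daughter pole formed at the
  mother's septum is the new pole; founders, whose pole history is
  unrecorded, are flagged and excluded from pole-resolved statistics.
- **Average kymographs** — per-cell axial fluorescence profiles, measured
  new pole → old pole over the cell cycle, are mapped by bilinear
  interpolation onto a common grid of relative cycle time × relative
  length and averaged; with per-cell row normalization the result is a
  localization-probability map.
- **Demographs** — single-timepoint population maps: per-cell profiles
  aligned by the brightest pole and stacked sorted by length (a cell-cycle
  proxy).
- **Pulse-chase growth quantification** — with pre-existing wall labeled
  and new polar material dark, the unlabeled margins of each cell's
  profile at birth and just before division measure the growth `g_old`,
  `g_new` each pole inserted in one generation; the old-pole share is
  `f_old = g_old / (g_old + g_new)` and the asymmetry index
  `a = (g_old − g_new) / (g_old + g_new)`.
- **Super-plot statistics** — per-cell values are reduced to replicate
  medians and compared across strains by a paired (repeated-measures)
  one-way ANOVA with replicate as block,
  `F = MS_strain / MS_error` on `(k−1, (k−1)(n−1))` degrees of freedom,
  with paired contrasts against a reference strain (Holm-adjusted).
- **A lineage simulator** — cells elongate at configurable per-pole rates
  with per-cell variability, divide at a length threshold, and render
  localization tracks, pulse-chase profile pairs, and toy two-channel
  microscopy frames with ground truth, so every stage of the analysis is
  verifiable by parameter recovery without any external data.

## Worked example

Measure per-pole growth in two simulated strains — a wild-type-like strain
that puts 70% of its elongation at the old pole, and a mutant-like strain
that grows symmetrically (`examples/03_pulse_chase_growth.py`):

```python
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
        measurements.append(pg.measure_polar_growth(birth, pre))
    share = np.median([m.old_pole_share for m in measurements])
    print(name, round(share, 2))   # -> WT 0.71, dlamA 0.5
```

The full script (`python examples/03_pulse_chase_growth.py`) prints:

```
    WT: median growth old pole 1.70 um, new pole 0.70 um; old-pole share 0.71 (truth 0.70); asymmetry index +0.42
 dlamA: median growth old pole 1.20 um, new pole 1.10 um; old-pole share 0.50 (truth 0.50); asymmetry index +0.00
```

The measured old-pole shares (0.71 and 0.50) recover the configured growth
splits (0.70 and 0.50) from noisy rendered profiles: the wild type inserts
most new wall at its old pole, the mutant splits growth evenly. Feeding the
same measurements from three replicates into the super-plot statistics
(`examples/04_superplot_stats.py`) yields replicate medians per strain and

```
Paired one-way ANOVA (replicate as block): F(2, 4) = 120.1818, p = 0.0002679
  WT vs dlamA: F(1, 2) = 120.1429, p = 0.008221, p_adj = 0.008221
  dlamA+pgfA vs dlamA: F(1, 2) = 400.0000, p = 0.002491, p_adj = 0.004981
```

— the strains with restored old-pole growth separate significantly from the
symmetric reference.

Each script in `examples/` demonstrates one capability end to end
(lineage simulation, average kymographs, pulse-chase growth, super plots,
demographs, image → profile extraction) and prints what its numbers mean.

## Command line

The same pipeline runs from a shell:

```bash
polegrowth run --config config.json --seed 1 --out-dir run1
polegrowth stats --measurements run1/measurements.tsv --reference-strain dlamA --out report.txt
```

`run` executes simulate → profile → kymo/demograph/growth → stats, writes
every intermediate as self-describing tab-separated text (plus PNG heatmaps
and optional TIFF stacks), and emits a manifest with SHA-256 digests of all
outputs; re-running with the same seed reproduces every file byte for byte.

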