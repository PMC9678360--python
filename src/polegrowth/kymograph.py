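"""Per-cell kymographs and cohort-averaged localization-probability maps.

Cells in a cohort differ in interdivision time and length, so their
kymographs are first mapped by bilinear interpolation onto a common grid of
relative cycle time (rows, 0 = birth, 1 = last frame before division) by
relative position (columns, 0 = new pole, 1 = old pole), then averaged.
With per-cell row-sum normalization the average reads as the probability of
finding the fluorophore at a given relative position at a given cycle
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import NEW_TO_OLD, CellCycleTrack, OrientationError

NORMALIZATIONS = ("none", "row_sum", "global_max")


@dataclass
class Kymograph:
    """One cell's intensity over (relative cycle time x relative position)."""

    values: np.ndarray  # (T, L)
    source_cell_id: int | str
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kymograph values must be a T x L matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kymograph values must be finite")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def L(self) -> int:
        return self.values.shape[1]


@dataclass
class AverageKymograph:
    values: np.ndarray
    n_cells: int
    cell_ids: list
    normalization: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def grid_normalize_track(track: CellCycleTrack, T: int = 50, L: int = 100) -> Kymograph:
    """Resample a track onto a T x L relative (cycle time x position) grid.

    Each frame's profile is linearly resampled to ``L`` bins over relative
    position [0, 1] (endpoints map exactly to the pole-tip samples); the
    resulting rows, located at relative times i/(F-1), are then linearly
    resampled along time to ``T`` bins over [0, 1]. No extrapolation occurs.
    """
    if track.orientation != NEW_TO_OLD:
        raise OrientationError(
            f"track of cell {track.cell_id!r} has orientation "
            f"{track.orientation!r}; kymographs require new_to_old"
        )
    if T < 2 or L < 2:
        raise ValueError("T and L must both be >= 2")
    F = track.n_frames
    pos_out = np.linspace(0.0, 1.0, L)
    rows = np.empty((F, L))
    for i, p in enumerate(track.profiles):
        pos_in = np.linspace(0.0, 1.0, p.length_px)
        rows[i] = np.interp(pos_out, pos_in, p.samples)
    t_in = np.linspace(0.0, 1.0, F)
    t_out = np.linspace(0.0, 1.0, T)
    out = np.empty((T, L))
    for j in range(L):
        out[:, j] = np.interp(t_out, t_in, rows[:, j])
    return Kymograph(out, track.cell_id, normalization="none")


def normalize_kymograph(kymo: Kymograph, mode: str) -> Kymograph:
    if mode not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {mode!r}; expected one of {NORMALIZATIONS}")
    if mode == "none":
        return Kymograph(kymo.values.copy(), kymo.source_cell_id, "none")
    v = kymo.values
    if mode == "row_sum":
        sums = v.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError(
                f"cell {kymo.source_cell_id!r}: non-positive row sum; "
                "row_sum normalization needs positive rows"
            )
        return Kymograph(v / sums, kymo.source_cell_id, "row_sum")
    m = v.max()
    if m <= 0:
        raise ValueError("global_max normalization needs a positive maximum")
    return Kymograph(v / m, kymo.source_cell_id, "global_max")


def average_kymographs(
    kymos: list[Kymograph], normalization: str = "row_sum"
) -> AverageKymograph:
    """Normalize each kymograph per the mode, then average pointwise."""
    if not kymos:
        raise ValueError("cannot average an empty list of kymographs")
    shapes = {k.values.shape for k in kymos}
    if len(shapes) != 1:
        raise ValueError(f"mixed kymograph grid shapes: {sorted(shapes)}")
    normed = [normalize_kymograph(k, normalization) for k in kymos]
    stack = np.stack([k.values for k in normed])
    return AverageKymograph(
        values=stack.mean(axis=0),
        n_cells=len(kymos),
        cell_ids=[k.source_cell_id for k in kymos],
        normalization=normalization,
    )


def pole_intensity_snapshot(
    kymos: list[Kymograph], cycle_fraction: float, pole_window: float = 0.1
) -> pd.DataFrame:
    """Per-cell old- and new-pole mean intensity at one cell-cycle stage.

    Takes each kymograph's time-row nearest ``cycle_fraction`` and averages
    the first (new pole) and last (old pole) ``ceil(pole_window * L)``
    position bins.
    """
    if not kymos:
        raise ValueError("empty kymograph list")
    if not 0.0 <= cycle_fraction <= 1.0:
        raise ValueError("cycle_fraction must lie in [0, 1]")
    if not 0.0 < pole_window <= 0.5:
        raise ValueError("pole_window must lie in (0, 0.5]")
    out = []
    for k in kymos:
        row_idx = int(round(cycle_fraction * (k.T - 1)))
        row = k.values[row_idx]
        w = int(np.ceil(pole_window * k.L))
        out.append(
            dict(
                cell_id=k.source_cell_id,
                new_pole_intensity=float(row[:w].mean()),
                old_pole_intensity=float(row[-w:].mean()),
            )
        )
    return pd.DataFrame(out)
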