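"""Demographs: single-timepoint population maps of axial fluorescence.

Each cell contributes one axial profile; profiles are aligned so the
brighter pole sits at the left edge, left-justified, padded on the right
with NaN, and stacked sorted by cell length — length standing in for
cell-cycle progression in a fixed population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import AxialProfile, orient_by_brightest_pole


@dataclass
class Demograph:
    """Rows: one per cell, brightest pole at column 0, NaN-padded, sorted by length."""

    rows: np.ndarray  # (n_cells, max_len), NaN = padding
    lengths_px: np.ndarray
    cell_ids: list
    terminal_fraction: float
    alignment_side: str = "left"

    @property
    def n_cells(self) -> int:
        return int(self.rows.shape[0])


def build_demograph(
    profiles: list[AxialProfile], terminal_fraction: float = 0.1
) -> Demograph:
    """Orient, pad, and length-sort a cohort of single-timepoint profiles.

    The sort is stable: cells of equal length keep their input order.
    Padding is NaN and must be excluded from any statistic computed on the
    rows.
    """
    if not profiles:
        raise ValueError("cannot build a demograph from an empty profile list")
    oriented = [orient_by_brightest_pole(p, terminal_fraction) for p in profiles]
    lengths = np.array([p.length_px for p in oriented])
    order = np.argsort(lengths, kind="stable")
    max_len = int(lengths.max())
    rows = np.full((len(oriented), max_len), np.nan)
    ids = []
    for out_i, in_i in enumerate(order):
        p = oriented[in_i]
        rows[out_i, : p.length_px] = p.samples
        ids.append(p.cell_id)
    return Demograph(
        rows=rows,
        lengths_px=lengths[order],
        cell_ids=ids,
        terminal_fraction=terminal_fraction,
    )
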