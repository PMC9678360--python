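"""Delimited-text, TIFF, and PNG input/output.

All tables are tab-separated text with a ``#``-prefixed header block naming
the columns, units, and conventions (0-based indices, profile index 0 = new
pole) plus the seed that produced them, so any table is self-describing and
round-trips losslessly through the module that wrote it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .demograph import Demograph
from .kymograph import AverageKymograph, Kymograph
from .profiles import AxialProfile
from .simulate import CellRecord

_CONVENTIONS = "0-based indices; profile sample index 0 = new pole unless orientation=unknown"


def _write_table(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# lineage tables


def write_lineage_table(records: list[CellRecord], path: str | Path, seed: int) -> None:
    df = pd.DataFrame(
        dict(
            cell_id=[r.cell_id for r in records],
            mother_id=[r.mother_id if r.mother_id is not None else -1 for r in records],
            birth_frame=[r.birth_frame for r in records],
            division_frame=[
                r.division_frame if r.division_frame is not None else -1 for r in records
            ],
            generation=[r.generation for r in records],
            old_pole_age_generations=[r.old_pole_age_generations for r in records],
            orientation_known=[int(r.orientation_known) for r in records],
            birth_length_um=[r.birth_length_um for r in records],
            division_cell_length_um=[r.division_cell_length_um for r in records],
            truth_growth_old_um=[r.truth_growth_old for r in records],
            truth_growth_new_um=[r.truth_growth_new for r in records],
            truth_septum_rel_position=[r.truth_septum_rel_position for r in records],
            x_new_birth=[r.x_new_birth for r in records],
            x_old_birth=[r.x_old_birth for r in records],
            septum_x=[r.septum_x for r in records],
            rate_old_um_per_frame=[r.rate_old for r in records],
            rate_new_um_per_frame=[r.rate_new for r in records],
        )
    )
    _write_table(
        df,
        Path(path),
        [
            "polegrowth lineage table",
            f"seed={seed}",
            _CONVENTIONS,
            "lengths and coordinates in um; -1 encodes 'none'",
            "septum position is a fraction of cell length measured from the new pole",
        ],
    )


def read_lineage_table(path: str | Path) -> list[CellRecord]:
    df = _read_table(Path(path))
    records = []
    for row in df.itertuples(index=False):
        div = None if row.division_frame == -1 else int(row.division_frame)
        n_growth = (div - row.birth_frame) if div is not None else 1
        total = row.rate_old_um_per_frame + row.rate_new_um_per_frame
        lengths = row.birth_length_um + total * np.arange(n_growth + 1)
        records.append(
            CellRecord(
                cell_id=int(row.cell_id),
                mother_id=None if row.mother_id == -1 else int(row.mother_id),
                birth_frame=int(row.birth_frame),
                division_frame=div,
                generation=int(row.generation),
                old_pole_age_generations=int(row.old_pole_age_generations),
                orientation_known=bool(row.orientation_known),
                length_series=lengths,
                truth_growth_old=float(row.truth_growth_old_um),
                truth_growth_new=float(row.truth_growth_new_um),
                truth_septum_rel_position=(
                    None if pd.isna(row.truth_septum_rel_position)
                    else float(row.truth_septum_rel_position)
                ),
                x_new_birth=float(row.x_new_birth),
                x_old_birth=float(row.x_old_birth),
                septum_x=None if pd.isna(row.septum_x) else float(row.septum_x),
                rate_old=float(row.rate_old_um_per_frame),
                rate_new=float(row.rate_new_um_per_frame),
            )
        )
    return records


# ---------------------------------------------------------------------------
# profile tables (long format)


def write_profiles_table(
    profiles: list[AxialProfile], path: str | Path, seed: int
) -> None:
    parts = []
    for p in profiles:
        parts.append(
            pd.DataFrame(
                dict(
                    cell_id=p.cell_id,
                    frame=p.frame,
                    sample_index=np.arange(p.length_px),
                    intensity=p.samples,
                    orientation=p.orientation,
                    pixel_size_um=p.pixel_size_um,
                    background_subtracted=int(p.background_subtracted),
                    end0_x=p.end0_x if p.end0_x is not None else np.nan,
                    end1_x=p.end1_x if p.end1_x is not None else np.nan,
                )
            )
        )
    df = pd.concat(parts, ignore_index=True)
    _write_table(
        df,
        Path(path),
        [
            "polegrowth axial profile table",
            f"seed={seed}",
            _CONVENTIONS,
            "end0_x/end1_x: axis coordinates (um) of the sample-0 / last-sample ends",
        ],
    )


def read_profiles_table(path: str | Path) -> list[AxialProfile]:
    df = _read_table(Path(path))
    profiles = []
    for (cid, frame), grp in df.groupby(["cell_id", "frame"], sort=True):
        grp = grp.sort_values("sample_index")
        first = grp.iloc[0]
        profiles.append(
            AxialProfile(
                cell_id=int(cid),
                frame=int(frame),
                samples=grp["intensity"].to_numpy(dtype=float),
                pixel_size_um=float(first["pixel_size_um"]),
                orientation=str(first["orientation"]),
                background_subtracted=bool(first["background_subtracted"]),
                end0_x=None if pd.isna(first["end0_x"]) else float(first["end0_x"]),
                end1_x=None if pd.isna(first["end1_x"]) else float(first["end1_x"]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# kymograph / demograph matrices


def write_kymograph_matrix(
    kymo: Kymograph | AverageKymograph, path: str | Path, seed: int
) -> None:
    if isinstance(kymo, AverageKymograph):
        ids = ",".join(str(i) for i in kymo.cell_ids)
        head = [f"average kymograph of n_cells={kymo.n_cells}", f"cell_ids={ids}"]
    else:
        head = [f"kymograph of cell {kymo.source_cell_id}"]
    T, L = kymo.values.shape
    header = (
        ["polegrowth kymograph matrix"]
        + head
        + [
            f"seed={seed}",
            f"T={T} L={L} normalization={kymo.normalization}",
            "rows: relative cycle time 0->1; columns: relative position, 0=new pole",
        ]
    )
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        np.savetxt(fh, kymo.values, delimiter="\t")


def read_kymograph_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", comments="#")


def write_demograph_matrix(demo: Demograph, path: str | Path, seed: int) -> None:
    df = pd.DataFrame(demo.rows)
    df.insert(0, "length_px", demo.lengths_px)
    df.insert(0, "cell_id", demo.cell_ids)
    _write_table(
        df,
        Path(path),
        [
            "polegrowth demograph matrix",
            f"seed={seed}",
            f"terminal_fraction={demo.terminal_fraction} alignment_side={demo.alignment_side}",
            "rows sorted by ascending length (cell-cycle proxy), brightest pole at column 0",
            "empty fields are padding and carry no intensity",
        ],
    )


# ---------------------------------------------------------------------------
# measurement tables


def write_measurements_table(df: pd.DataFrame, path: str | Path, seed: int) -> None:
    _write_table(
        df,
        Path(path),
        [
            "polegrowth pulse-chase measurement table",
            f"seed={seed}",
            "growth/elongation in um; asymmetry = (old-new)/(old+new); NaN = excluded",
        ],
    )


def read_measurements_table(path: str | Path) -> pd.DataFrame:
    df = _read_table(Path(path))
    for col in ("strain", "replicate", "qc_flags"):
        if col in df:
            df[col] = df[col].fillna("").astype(str)
    return df


# ---------------------------------------------------------------------------
# images


def write_tiff_stack(frames: list[np.ndarray], path: str | Path, as_uint16: bool = False) -> None:
    import tifffile

    stack = np.stack(frames)
    if as_uint16:
        stack = np.clip(stack, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    else:
        stack = stack.astype(np.float32)
    tifffile.imwrite(path, stack)


def read_tiff_stack(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def render_heatmap_png(
    values: np.ndarray, path: str | Path, title: str = "", cmap: str = "viridis"
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(values, aspect="auto", origin="upper", cmap=cmap)
    ax.set_xlabel("relative position (new pole -> old pole)")
    ax.set_ylabel("relative cycle time (birth -> division)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": "polegrowth"})
    plt.close(fig)
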