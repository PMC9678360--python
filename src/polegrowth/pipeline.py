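"""End-to-end pipeline: simulate -> profile -> kymo / demograph / growth -> stats.

A single top-level seed reproduces an entire run: every (strain, replicate)
condition receives a deterministic sub-seed, every output is delimited text
with a commented header, and the run manifest records a SHA-256 digest of
each file so that any nondeterminism is detectable by re-running.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pgio
from .config import ConfigError, SimulationConfig
from .demograph import build_demograph
from .growth import measure_polar_growth, measurements_to_frame
from .kymograph import average_kymographs, grid_normalize_track, pole_intensity_snapshot
from .profiles import NEW_TO_OLD, group_tracks, orient_track_new_to_old
from .simulate import render_localization_track, render_pulse_chase_pair, simulate_lineage
from .superplot import superplot

logger = logging.getLogger(__name__)

STAGES = ("simulate", "profile", "kymo", "demograph", "growth", "stats")
#: upstream stage each stage's inputs come from
_UPSTREAM = {
    "profile": "simulate",
    "kymo": "profile",
    "demograph": "profile",
    "growth": "simulate",
    "stats": "growth",
}

ARTIFACT_VERSION = "0.1.0"


class MissingUpstreamError(RuntimeError):
    def __init__(self, stage: str, upstream: str):
        super().__init__(
            f"stage {stage!r} found no inputs; run stage {upstream!r} first"
        )
        self.upstream = upstream


@dataclass(frozen=True)
class PipelineConfig:
    """Whole-run configuration: base simulation plus per-strain overrides."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    strains: dict = field(default_factory=lambda: {"WT": {}})
    replicates: int = 1
    grid_T: int = 50
    grid_L: int = 100
    normalization: str = "row_sum"
    snapshot_fraction: float = 0.25
    pole_window: float = 0.1
    terminal_fraction: float = 0.1
    threshold_fraction: float = 0.5
    value_column: str = "growth_old_um"
    reference_strain: str | None = None
    adjust: str = "holm"
    emit_images: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def condition_config(self, strain: str, replicate: int, seed: int) -> SimulationConfig:
        overrides = dict(self.strains[strain])
        strain_idx = list(self.strains).index(strain)
        sub_seed = int(
            np.random.SeedSequence([seed, strain_idx, replicate]).generate_state(1)[0]
            % (2**31)
        )
        base = self.simulation.to_dict()
        base.update(overrides)
        base["seed"] = sub_seed
        return SimulationConfig.from_dict(base)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    config: dict
    stages: list[str]
    artifact_version: str
    file_digests: dict
    timestamps: dict | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _conditions(cfg: PipelineConfig):
    for strain in cfg.strains:
        for rep in range(1, cfg.replicates + 1):
            yield strain, rep


def _stage_simulate(cfg: PipelineConfig, seed: int, out: Path) -> None:
    for strain, rep in _conditions(cfg):
        sim_cfg = cfg.condition_config(strain, rep, seed)
        records = simulate_lineage(sim_cfg)
        pgio.write_lineage_table(records, out / f"lineage_{strain}_r{rep}.tsv", seed)
        loc_profiles = []
        pulse_profiles = []
        n_skipped = 0
        for rec in records:
            if rec.n_life_frames < 2:
                n_skipped += 1
                continue
            track = render_localization_track(rec, sim_cfg)
            loc_profiles.extend(track.profiles)
            birth, pre = render_pulse_chase_pair(rec, sim_cfg)
            pulse_profiles.extend([birth, pre])
        if n_skipped:
            logger.warning("%s r%d: skipped %d cell(s) with <2 frames", strain, rep, n_skipped)
        pgio.write_profiles_table(loc_profiles, out / f"locprofiles_{strain}_r{rep}.tsv", seed)
        pgio.write_profiles_table(pulse_profiles, out / f"pulse_{strain}_r{rep}.tsv", seed)
        if cfg.emit_images:
            from .simulate import render_frame_image

            frames = sorted({p.frame for p in loc_profiles})[:5]
            phase, fluor, masks = [], [], []
            for f in frames:
                img = render_frame_image(records, f, sim_cfg)
                phase.append(img.phase)
                fluor.append(img.fluorescence)
                masks.append(img.mask)
            pgio.write_tiff_stack(phase, out / f"images_{strain}_r{rep}_phase.tif")
            pgio.write_tiff_stack(fluor, out / f"images_{strain}_r{rep}_fluor.tif")
            pgio.write_tiff_stack(masks, out / f"images_{strain}_r{rep}_mask.tif", as_uint16=True)


def _stage_profile(cfg: PipelineConfig, seed: int, out: Path) -> None:
    any_input = False
    for strain, rep in _conditions(cfg):
        src = out / f"locprofiles_{strain}_r{rep}.tsv"
        lineage_path = out / f"lineage_{strain}_r{rep}.tsv"
        if not src.exists() or not lineage_path.exists():
            continue
        any_input = True
        profiles = pgio.read_profiles_table(src)
        lineage = pgio.read_lineage_table(lineage_path)
        tracks = group_tracks(profiles)
        oriented = []
        n_founders = 0
        for tr in tracks:
            tr = orient_track_new_to_old(tr, lineage)
            if tr.orientation != NEW_TO_OLD:
                n_founders += 1
                continue
            oriented.extend(tr.profiles)
        logger.info(
            "%s r%d: oriented %d track(s), excluded %d founder(s)",
            strain, rep, len(tracks) - n_founders, n_founders,
        )
        pgio.write_profiles_table(oriented, out / f"oriented_{strain}_r{rep}.tsv", seed)
    if not any_input:
        raise MissingUpstreamError("profile", "simulate")


def _oriented_tracks(cfg: PipelineConfig, out: Path, stage: str):
    per_strain: dict[str, list] = {s: [] for s in cfg.strains}
    any_input = False
    for strain, rep in _conditions(cfg):
        src = out / f"oriented_{strain}_r{rep}.tsv"
        if not src.exists():
            continue
        any_input = True
        per_strain[strain].extend(group_tracks(pgio.read_profiles_table(src)))
    if not any_input:
        raise MissingUpstreamError(stage, "profile")
    return per_strain


def _stage_kymo(cfg: PipelineConfig, seed: int, out: Path) -> None:
    per_strain = _oriented_tracks(cfg, out, "kymo")
    for strain, tracks in per_strain.items():
        if not tracks:
            continue
        kymos = [grid_normalize_track(t, cfg.grid_T, cfg.grid_L) for t in tracks]
        avg = average_kymographs(kymos, cfg.normalization)
        pgio.write_kymograph_matrix(avg, out / f"avgkymo_{strain}.tsv", seed)
        pgio.render_heatmap_png(
            avg.values, out / f"avgkymo_{strain}.png",
            title=f"{strain}: average kymograph (n={avg.n_cells})",
        )
        snap = pole_intensity_snapshot(kymos, cfg.snapshot_fraction, cfg.pole_window)
        pgio._write_table(
            snap, out / f"snapshot_{strain}.tsv",
            [
                "polegrowth pole-intensity snapshot",
                f"seed={seed}",
                f"cycle_fraction={cfg.snapshot_fraction} pole_window={cfg.pole_window}",
            ],
        )


def _stage_demograph(cfg: PipelineConfig, seed: int, out: Path) -> None:
    per_strain = _oriented_tracks(cfg, out, "demograph")
    for strain, tracks in per_strain.items():
        if not tracks:
            continue
        # one single-timepoint profile per cell: the mid-cycle frame
        snapshot = [t.profiles[t.n_frames // 2] for t in tracks]
        demo = build_demograph(snapshot, cfg.terminal_fraction)
        pgio.write_demograph_matrix(demo, out / f"demograph_{strain}.tsv", seed)
        pgio.render_heatmap_png(
            demo.rows, out / f"demograph_{strain}.png",
            title=f"{strain}: demograph (n={demo.n_cells})", cmap="magma",
        )


def _stage_growth(cfg: PipelineConfig, seed: int, out: Path) -> None:
    all_ms = []
    any_input = False
    for strain, rep in _conditions(cfg):
        src = out / f"pulse_{strain}_r{rep}.tsv"
        lineage_path = out / f"lineage_{strain}_r{rep}.tsv"
        if not src.exists() or not lineage_path.exists():
            continue
        any_input = True
        lineage = {r.cell_id: r for r in pgio.read_lineage_table(lineage_path)}
        profiles = pgio.read_profiles_table(src)
        by_cell: dict = {}
        for p in profiles:
            by_cell.setdefault(p.cell_id, []).append(p)
        n_excluded = 0
        for cid, pair in sorted(by_cell.items()):
            rec = lineage.get(cid)
            if rec is None or not rec.orientation_known:
                n_excluded += 1
                continue
            pair.sort(key=lambda p: p.frame)
            m = measure_polar_growth(
                pair[0], pair[-1],
                threshold_fraction=cfg.threshold_fraction,
                background=cfg.simulation.background,
                strain=strain, replicate=f"r{rep}",
            )
            all_ms.append(m)
        logger.info(
            "%s r%d: measured %d cell(s), excluded %d with unknown pole identity",
            strain, rep, len(by_cell) - n_excluded, n_excluded,
        )
    if not any_input:
        raise MissingUpstreamError("growth", "simulate")
    df = measurements_to_frame(all_ms)
    # also report growth as a percentage of birth-to-division elongation
    pgio.write_measurements_table(df, out / "measurements.tsv", seed)


def _stage_stats(cfg: PipelineConfig, seed: int, out: Path) -> None:
    src = out / "measurements.tsv"
    if not src.exists():
        raise MissingUpstreamError("stats", "growth")
    df = pgio.read_measurements_table(src)
    if df["strain"].nunique() < 2 or df["replicate"].nunique() < 2:
        logger.warning(
            "stats: need >= 2 strains and >= 2 replicates for the paired ANOVA; "
            "writing replicate medians only"
        )
        medians = df.groupby(["strain", "replicate"])[cfg.value_column].median()
        (out / "superplot.txt").write_text(
            "Replicate medians (insufficient design for paired ANOVA):\n"
            + medians.to_string() + "\n"
        )
        return
    summary = superplot(
        df, cfg.value_column,
        reference=cfg.reference_strain, adjust=cfg.adjust,
    )
    (out / "superplot.txt").write_text(summary.report() + "\n")
    pgio._write_table(
        summary.medians.reset_index(),
        out / "superplot_medians.tsv",
        ["polegrowth super-plot replicate medians", f"seed={seed}",
         f"value_column={cfg.value_column}"],
    )


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "profile": _stage_profile,
    "kymo": _stage_kymo,
    "demograph": _stage_demograph,
    "growth": _stage_growth,
    "stats": _stage_stats,
}


def run_pipeline(
    config: PipelineConfig | str | Path,
    stages: list[str] | None = None,
    out_dir: str | Path = "polegrowth_run",
    seed: int | None = None,
    include_timestamps: bool = False,
) -> RunManifest:
    """Run the requested stages in order and write a reproducibility manifest.

    ``seed`` overrides the simulation seed from the config. A stage whose
    inputs are missing aborts with an error naming the upstream stage;
    partial outputs of completed stages are retained.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_json(config)
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage name(s): {unknown}; valid stages: {STAGES}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    if seed is None:
        seed = config.simulation.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timestamps = {} if include_timestamps else None
    for stage in stages:
        logger.info("running stage %s (seed=%d)", stage, seed)
        _STAGE_FNS[stage](config, seed, out)
        if timestamps is not None:
            timestamps[stage] = time.time()
    digests = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        seed=seed,
        config=config.to_dict(),
        stages=stages,
        artifact_version=ARTIFACT_VERSION,
        file_digests=digests,
        timestamps=timestamps,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
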