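"""Lineage simulation of asymmetric polar growth, with fluorescence renderers.

The model: a rod-shaped cell elongates only at its poles, gaining
``rate_old`` um/frame at the established (old) pole and ``rate_new``
um/frame at the pole formed at the previous division.  Division fires at
the first frame whose length reaches ``division_length`` and places the
septum at a truncated-normal relative position; both daughters inherit one
pre-existing pole (its age incremented) and one brand-new pole (age 1).
With the per-cell variability switched off (``rate_cv = pole_share_sd = 0``)
the old-pole share of every cell's elongation is exactly
``rate_old / (rate_old + rate_new)`` — this is what makes the simulation
usable as ground truth for parameter-recovery tests of the downstream
measurement code; with variability on, cohorts gain the cell-to-cell spread
real time-lapse data shows, which is what gives replicate medians a
non-degenerate sampling distribution for the super-plot statistics.

Three renderers paint observables on top of the lineage: per-frame axial
fluorescence profiles following a configurable localization program
(old-pole accumulation, late septal relocalization, ...), pulse-chase
profile pairs in which pre-existing wall is labeled and polar extensions are
dark, and toy two-channel microscopy frames with ground-truth masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .config import ConfigError, SimulationConfig
from .profiles import NEW_TO_OLD, AxialProfile, CellCycleTrack

logger = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """Cells could not be placed without overlap within the retry budget."""


@dataclass
class CellRecord:
    """One cell's entry in a simulated lineage.

    ``length_series[k]`` is the length at frame ``birth_frame + k``; the
    series runs up to and including the division frame (so that the recorded
    per-pole growth sums exactly to the length gained between birth and
    division), or up to the simulation frame cap for cells that never
    divide. ``x_new_birth`` / ``x_old_birth`` are 1-D axis coordinates of the
    two pole tips at birth; the poles move apart along this axis as the cell
    grows, and ``septum_x`` records where the septum formed.
    """

    cell_id: int
    mother_id: int | None
    birth_frame: int
    division_frame: int | None
    generation: int
    old_pole_age_generations: int
    orientation_known: bool
    length_series: np.ndarray
    truth_growth_old: float
    truth_growth_new: float
    truth_septum_rel_position: float | None
    x_new_birth: float
    x_old_birth: float
    septum_x: float | None
    rate_old: float
    rate_new: float

    @property
    def n_life_frames(self) -> int:
        """Frames from birth to the last frame before division (inclusive)."""
        if self.division_frame is None:
            return int(self.length_series.size)
        return int(self.division_frame - self.birth_frame)

    @property
    def birth_length_um(self) -> float:
        return float(self.length_series[0])

    @property
    def division_cell_length_um(self) -> float:
        return float(self.length_series[-1])

    @property
    def truth_old_pole_share(self) -> float:
        total = self.truth_growth_old + self.truth_growth_new
        return self.truth_growth_old / total if total > 0 else np.nan

    def pole_positions_at(self, k: int) -> tuple[float, float]:
        """(x_new, x_old) axis coordinates after k frames of growth."""
        direction = np.sign(self.x_new_birth - self.x_old_birth)
        x_new = self.x_new_birth + direction * self.rate_new * k
        x_old = self.x_old_birth - direction * self.rate_old * k
        return float(x_new), float(x_old)


def _draw_septum_fraction(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    """Relative septum position from the new pole, truncated to (0.2, 0.8)."""
    if cfg.septum_rel_position_sd == 0:
        return float(np.clip(cfg.septum_rel_position_mean, 0.2, 0.8))
    for _ in range(1000):
        s = rng.normal(cfg.septum_rel_position_mean, cfg.septum_rel_position_sd)
        if 0.2 < s < 0.8:
            return float(s)
    raise ConfigError("septum draw failed: mean/sd incompatible with (0.2, 0.8)")


def simulate_lineage(config: SimulationConfig) -> list[CellRecord]:
    """Simulate ``n_generations`` of polar-growing cells from ``n_founders``.

    Founders are generation 1 and carry ``orientation_known=False``: without
    a recorded division their new/old pole identity is a convention, not a
    measurement, and pole-resolved statistics exclude them by default.
    """
    rng = np.random.default_rng(config.seed)
    total_rate = config.rate_old + config.rate_new
    records: list[CellRecord] = []
    next_id = 0
    queue: list[dict] = []
    spacing = 10.0 * config.division_length
    for i in range(config.n_founders):
        x0 = i * spacing
        new_on_left = bool(rng.integers(2))
        x_new = x0 if new_on_left else x0 + config.birth_length
        x_old = x0 + config.birth_length if new_on_left else x0
        queue.append(
            dict(
                mother_id=None,
                birth_frame=0,
                birth_length=config.birth_length,
                generation=1,
                old_pole_age=1,
                orientation_known=False,
                x_new=x_new,
                x_old=x_old,
            )
        )

    base_share = config.rate_old / total_rate if total_rate > 0 else 0.5

    while queue:
        info = queue.pop(0)
        cid = next_id
        next_id += 1
        L0 = info["birth_length"]
        bf = info["birth_frame"]
        # per-cell biological variability: a gamma-distributed multiplier on
        # the total rate and Gaussian jitter on the old-pole share
        mult = 1.0
        if config.rate_cv > 0 and total_rate > 0:
            cv2 = config.rate_cv**2
            mult = float(rng.gamma(1.0 / cv2, cv2))
        share = base_share
        if config.pole_share_sd > 0 and total_rate > 0:
            share = float(np.clip(rng.normal(base_share, config.pole_share_sd), 0.0, 1.0))
        cell_total = total_rate * mult
        cell_rate_old = share * cell_total
        cell_rate_new = (1.0 - share) * cell_total
        # frames until division: first k >= 1 with L0 + k*cell_total >= threshold
        if cell_total > 0:
            k_div = max(1, int(np.ceil((config.division_length - L0) / cell_total)))
        else:
            k_div = None
        if k_div is not None and bf + k_div <= config.max_frames:
            lengths = L0 + cell_total * np.arange(k_div + 1)
            div_frame = bf + k_div
            n_growth = k_div
            s = _draw_septum_fraction(config, rng)
        else:
            n_obs = (config.max_frames - bf) if cell_total > 0 else config.max_frames
            n_obs = max(1, n_obs)
            lengths = (
                L0 + cell_total * np.arange(n_obs + 1)
                if cell_total > 0
                else np.full(n_obs, L0)
            )
            div_frame = None
            n_growth = lengths.size - 1
            s = None
        rec = CellRecord(
            cell_id=cid,
            mother_id=info["mother_id"],
            birth_frame=bf,
            division_frame=div_frame,
            generation=info["generation"],
            old_pole_age_generations=info["old_pole_age"],
            orientation_known=info["orientation_known"],
            length_series=np.asarray(lengths, dtype=float),
            truth_growth_old=cell_rate_old * n_growth,
            truth_growth_new=cell_rate_new * n_growth,
            truth_septum_rel_position=s,
            x_new_birth=info["x_new"],
            x_old_birth=info["x_old"],
            septum_x=None,
            rate_old=cell_rate_old,
            rate_new=cell_rate_new,
        )
        if div_frame is not None:
            x_new_d, x_old_d = rec.pole_positions_at(k_div)
            septum_x = x_new_d + s * (x_old_d - x_new_d)
            rec.septum_x = septum_x
            if info["generation"] < config.n_generations:
                # daughter on the mother's new-pole side: inherits the mother's
                # new pole (now one generation old -> age 2); its own new pole
                # forms at the septum
                queue.append(
                    dict(
                        mother_id=cid,
                        birth_frame=div_frame,
                        birth_length=s * rec.division_cell_length_um,
                        generation=info["generation"] + 1,
                        old_pole_age=2,
                        orientation_known=True,
                        x_new=septum_x,
                        x_old=x_new_d,
                    )
                )
                # daughter on the old-pole side keeps the mother's old pole
                queue.append(
                    dict(
                        mother_id=cid,
                        birth_frame=div_frame,
                        birth_length=(1.0 - s) * rec.division_cell_length_um,
                        generation=info["generation"] + 1,
                        old_pole_age=info["old_pole_age"] + 1,
                        orientation_known=True,
                        x_new=septum_x,
                        x_old=x_old_d,
                    )
                )
        records.append(rec)
    logger.info(
        "simulated %d cells over %d generation(s) (seed=%d)",
        len(records), config.n_generations, config.seed,
    )
    return records


def simulate_cohort(config: SimulationConfig, n_cells: int) -> list[CellRecord]:
    """Simulate enough founders to yield ``n_cells`` pole-resolved cells.

    Returns the first ``n_cells`` non-founder records (cells followed from a
    recorded birth to division, so their pole identity is known), mirroring
    cohorts assembled by following individual cells in a time lapse.
    """
    n_founders = max(1, -(-n_cells // 2))
    cfg = config.replace(n_founders=n_founders, n_generations=2)
    records = [r for r in simulate_lineage(cfg) if r.mother_id is not None]
    if len(records) < n_cells:
        raise ValueError(f"cohort came up short: {len(records)} < {n_cells}")
    return records[:n_cells]


# ---------------------------------------------------------------------------
# localization rendering


def _gaussian_spot(n: int, center: float, sigma: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    if sigma <= 0:
        out = np.zeros(n)
        c = int(round(center))
        if 0 <= c < n:
            out[c] = 1.0
        return out
    return np.exp(-0.5 * ((i - center) / sigma) ** 2)


def _profile_npx(length_um: float, pixel_size_um: float) -> int:
    return max(2, int(round(length_um / pixel_size_um)))


def _localization_profile(
    cfg: SimulationConfig, n: int, tau: float, septum_rel: float
) -> np.ndarray:
    """Noise-free axial signal for one frame (index 0 = new pole)."""
    mode = cfg.localization_mode
    amp_old = amp_new = amp_sep = 0.0
    flat = 0.0
    if mode == "old_pole":
        amp_old = cfg.signal
    elif mode == "new_pole":
        amp_new = cfg.signal
    elif mode == "bipolar":
        amp_old = cfg.signal * cfg.old_pole_signal_scale
        amp_new = cfg.signal * cfg.new_pole_signal_scale
    elif mode == "midcell_late":
        if tau >= cfg.septal_onset_fraction:
            amp_sep = cfg.signal
    elif mode == "uniform":
        flat = cfg.signal
    if mode in ("old_pole", "new_pole", "bipolar") and cfg.septal_transfer_fraction > 0:
        if tau >= cfg.septal_onset_fraction:
            f = cfg.septal_transfer_fraction
            amp_sep = f * (amp_old + amp_new)
            amp_old *= 1.0 - f
            amp_new *= 1.0 - f
    prof = np.full(n, cfg.background + flat, dtype=float)
    if amp_old:
        prof += amp_old * _gaussian_spot(n, n - 1, cfg.spot_sigma_px)
    if amp_new:
        prof += amp_new * _gaussian_spot(n, 0, cfg.spot_sigma_px)
    if amp_sep:
        prof += amp_sep * _gaussian_spot(n, septum_rel * (n - 1), cfg.spot_sigma_px)
    return prof


def render_localization_track(
    record: CellRecord, config: SimulationConfig
) -> CellCycleTrack:
    """Render one profile per frame of the cell's life (birth to pre-division).

    The profiles follow the configured localization program — e.g. an
    old-pole spot that, after ``septal_onset_fraction`` of the cycle, hands
    ``septal_transfer_fraction`` of its amplitude to a septal spot — with
    Gaussian noise of s.d. ``noise_sd`` on top of ``background``. Output is
    oriented new->old with per-frame pole axis coordinates attached.
    """
    F = record.n_life_frames
    if F < 2:
        raise ValueError(f"cell {record.cell_id} lives < 2 frames; cannot render a track")
    rng = np.random.default_rng([config.seed, 17, record.cell_id])
    septum_rel = (
        record.truth_septum_rel_position
        if record.truth_septum_rel_position is not None
        else config.septum_rel_position_mean
    )
    profiles = []
    for k in range(F):
        tau = k / (F - 1)
        n = _profile_npx(record.length_series[k], config.pixel_size_um)
        prof = _localization_profile(config, n, tau, septum_rel)
        if config.noise_sd > 0:
            prof = prof + rng.normal(0.0, config.noise_sd, size=n)
        x_new, x_old = record.pole_positions_at(k)
        profiles.append(
            AxialProfile(
                cell_id=record.cell_id,
                frame=record.birth_frame + k,
                samples=prof,
                pixel_size_um=config.pixel_size_um,
                orientation=NEW_TO_OLD,
                end0_x=x_new,
                end1_x=x_old,
            )
        )
    return CellCycleTrack(record.cell_id, profiles)


# ---------------------------------------------------------------------------
# pulse-chase rendering


def render_pulse_chase_pair(
    record: CellRecord,
    config: SimulationConfig,
    offset_um: float | None = None,
) -> tuple[AxialProfile, AxialProfile]:
    """Render the (birth, pre-division) profile pair of a pulse-chase assay.

    All wall present at staining is bright (``background + label_intensity``);
    material inserted at the poles afterwards is dark (``background``). At
    birth the labeled region spans the whole cell minus ``offset_um`` of
    growth already accrued per pole since staining (default 0); at the frame
    before division it is flanked by dark margins equal to the per-pole
    growth accrued since birth. Noise is added last.
    """
    if offset_um is None:
        offset_um = config.pulse_chase_offset_um
    if offset_um < 0:
        raise ConfigError("pulse-chase offset must be >= 0")
    if config.label_intensity <= 0:
        raise ConfigError("label level must exceed background")
    F = record.n_life_frames
    if F < 2:
        raise ValueError(f"cell {record.cell_id} has < 2 frames")
    rng = np.random.default_rng([config.seed, 23, record.cell_id])
    px = config.pixel_size_um

    def make(length_um: float, margin_new_um: float, margin_old_um: float, frame_k: int):
        n = _profile_npx(length_um, px)
        m_new = int(round(margin_new_um / px))
        m_old = int(round(margin_old_um / px))
        prof = np.full(n, config.background, dtype=float)
        lo, hi = m_new, n - m_old
        if hi > lo:
            prof[lo:hi] += config.label_intensity
        if config.noise_sd > 0:
            prof = prof + rng.normal(0.0, config.noise_sd, size=n)
        x_new, x_old = record.pole_positions_at(frame_k)
        return AxialProfile(
            cell_id=record.cell_id,
            frame=record.birth_frame + frame_k,
            samples=prof,
            pixel_size_um=px,
            orientation=NEW_TO_OLD,
            end0_x=x_new,
            end1_x=x_old,
        )

    birth = make(record.length_series[0], offset_um, offset_um, 0)
    k_pre = F - 1
    pre = make(
        record.length_series[k_pre],
        offset_um + record.rate_new * k_pre,
        offset_um + record.rate_old * k_pre,
        k_pre,
    )
    return birth, pre


# ---------------------------------------------------------------------------
# toy frame rendering


@dataclass
class FrameImage:
    """One rendered two-channel frame with its ground-truth label mask."""

    phase: np.ndarray
    fluorescence: np.ndarray
    mask: np.ndarray
    prepsf_fluor_sum: float
    cell_ids: list[int] = field(default_factory=list)


PHASE_AMPLITUDE = 200.0


def cells_alive_at(records: Sequence[CellRecord], frame: int) -> list[CellRecord]:
    """Cells present at a frame (a mother's last frame is the one before division)."""
    out = []
    for r in records:
        last = (
            r.division_frame - 1
            if r.division_frame is not None
            else r.birth_frame + r.length_series.size - 1
        )
        if r.birth_frame <= frame <= last:
            out.append(r)
    return out


def render_frame_image(
    records: Sequence[CellRecord],
    frame: int,
    config: SimulationConfig,
    shape: tuple[int, int] | None = None,
    max_retries: int = 200,
) -> FrameImage:
    """Render all live cells at ``frame`` as spherocylinders on a blank field.

    Cells are placed at random positions and angles without overlap (snapshot
    rendering: placements are independent between frames); the fluorescence
    channel paints each cell's axial localization signal along its axis, both
    channels are blurred with an isotropic Gaussian PSF, and the ground-truth
    label mask is returned alongside.
    """
    live = cells_alive_at(records, frame)
    rng = np.random.default_rng([config.seed, 31, frame])
    px = config.pixel_size_um
    radius_px = max(1.0, config.cell_radius_um / px)
    margin = int(np.ceil(4 * config.psf_sigma_px + radius_px)) + 2
    if shape is None:
        max_len = max(
            [config.division_length / px] + [r.division_cell_length_um / px for r in live]
        )
        side = int(np.ceil(np.sqrt(max(1, len(live))) * (max_len + 4 * radius_px))) + 2 * margin
        shape = (max(64, side), max(64, side))
    H, W = shape
    phase = np.zeros((H, W), dtype=float)
    fluor = np.zeros((H, W), dtype=float)
    mask = np.zeros((H, W), dtype=np.uint16)
    occupied = np.zeros((H, W), dtype=bool)
    rows, cols = np.mgrid[0:H, 0:W].astype(float)

    for label_id, rec in enumerate(live, start=1):
        k = frame - rec.birth_frame
        length_px = rec.length_series[k] / px
        half = max(0.0, length_px / 2.0 - radius_px)
        placed = False
        for _ in range(max_retries):
            cy = rng.uniform(margin + half, H - margin - half)
            cx = rng.uniform(margin + half, W - margin - half)
            theta = rng.uniform(0, np.pi)
            ux, uy = np.cos(theta), np.sin(theta)
            # endpoints of the axis segment (centerline of the spherocylinder)
            p0 = np.array([cy - half * uy, cx - half * ux])
            p1 = np.array([cy + half * uy, cx + half * ux])
            d = p1 - p0
            L2 = float(d @ d)
            rel_r, rel_c = rows - p0[0], cols - p0[1]
            t = (rel_r * d[0] + rel_c * d[1]) / L2 if L2 > 0 else np.zeros_like(rel_r)
            t = np.clip(t, 0.0, 1.0)
            dist2 = (rel_r - t * d[0]) ** 2 + (rel_c - t * d[1]) ** 2
            foot = dist2 <= radius_px**2
            if not (occupied & foot).any():
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {rec.cell_id} at frame {frame} "
                f"within {max_retries} retries"
            )
        occupied |= foot
        mask[foot] = label_id
        phase[foot] = PHASE_AMPLITUDE
        # axial position of every footprint pixel, in profile coordinates
        # (axis coordinate 0 = new pole end, chosen as the p0 end)
        n = _profile_npx(rec.length_series[k], px)
        septum_rel = (
            rec.truth_septum_rel_position
            if rec.truth_septum_rel_position is not None
            else config.septum_rel_position_mean
        )
        F_life = max(2, rec.n_life_frames)
        tau = k / (F_life - 1)
        axial = _localization_profile(config, n, tau, septum_rel) - config.background
        idx = np.clip((t[foot] * (n - 1)).round().astype(int), 0, n - 1)
        fluor[foot] = axial[idx]

    prepsf_sum = float(fluor.sum())
    if config.psf_sigma_px > 0:
        phase = ndimage.gaussian_filter(phase, config.psf_sigma_px, mode="constant")
        fluor = ndimage.gaussian_filter(fluor, config.psf_sigma_px, mode="constant")
    phase = phase + config.background
    fluor = fluor + config.background
    if config.noise_sd > 0:
        phase = phase + rng.normal(0.0, config.noise_sd, size=phase.shape)
        fluor = fluor + rng.normal(0.0, config.noise_sd, size=fluor.shape)
    return FrameImage(phase, fluor, mask, prepsf_sum, [r.cell_id for r in live])
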