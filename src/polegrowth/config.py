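"""Simulation configuration.

Mycobacteria elongate from their poles, and the two poles grow at unequal
rates: the established "old" pole (inherited from an earlier generation)
normally outgrows the "new" pole formed at the last division.  The
configuration below parameterises a minimal lineage model of that process —
constant per-pole elongation rates, division triggered by a length
threshold, and a septum placed at a (truncated-normal) relative position —
together with the fluorescence programs the renderers paint on top of it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

LOCALIZATION_MODES = ("old_pole", "new_pole", "bipolar", "midcell_late", "uniform")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the polar-growth lineage simulation.

    Lengths are in micrometres, rates in micrometres per frame (one frame
    corresponds to ``frame_interval_min`` minutes of wall-clock time),
    intensities in arbitrary camera units.
    """

    #: elongation added at the old pole per frame (um/frame)
    rate_old: float = 0.14
    #: elongation added at the new pole per frame (um/frame)
    rate_new: float = 0.06
    #: per-cell coefficient of variation of the total elongation rate
    #: (gamma-distributed multiplier with mean 1); 0 disables the jitter and
    #: makes per-pole growth fractions exact
    rate_cv: float = 0.15
    #: per-cell s.d. of the old-pole growth share around rate_old/(rate_old+rate_new)
    pole_share_sd: float = 0.03
    #: cell length at birth for founder cells (um)
    birth_length: float = 2.5
    #: division is triggered at the first frame with length >= this (um)
    division_length: float = 5.0
    #: mean relative septum position, measured from the new pole, in (0,1)
    septum_rel_position_mean: float = 0.5
    #: s.d. of the relative septum position (draw truncated to (0.2, 0.8))
    septum_rel_position_sd: float = 0.05
    #: minutes between consecutive frames
    frame_interval_min: float = 15.0
    #: physical pixel size (um/pixel)
    pixel_size_um: float = 0.1
    #: fluorescence program: old_pole | new_pole | bipolar | midcell_late | uniform
    localization_mode: str = "old_pole"
    #: cell-cycle fraction at which septal relocalization begins
    septal_onset_fraction: float = 0.75
    #: fraction of the polar signal moved to the septum after onset
    septal_transfer_fraction: float = 0.0
    #: peak amplitude of a localization spot (intensity units)
    signal: float = 100.0
    #: per-pole amplitude scales applied in bipolar mode (old pole, new pole)
    old_pole_signal_scale: float = 1.0
    new_pole_signal_scale: float = 0.3
    #: Gaussian spot s.d. along the axis (pixels)
    spot_sigma_px: float = 2.0
    #: pulse-chase label plateau intensity above background
    label_intensity: float = 100.0
    #: growth already accrued between staining and the birth frame (um/pole)
    pulse_chase_offset_um: float = 0.0
    #: cell radius for image rendering (um)
    cell_radius_um: float = 0.35
    #: isotropic Gaussian PSF s.d. for image rendering (pixels)
    psf_sigma_px: float = 1.0
    #: s.d. of additive Gaussian intensity noise
    noise_sd: float = 0.0
    #: constant intensity background
    background: float = 0.0
    #: number of founder cells
    n_founders: int = 1
    #: number of generations to simulate (founders are generation 1)
    n_generations: int = 2
    #: hard cap on the simulated frame range
    max_frames: int = 400
    #: seed for the single pseudo-random generator driving all draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_old < 0 or self.rate_new < 0:
            raise ConfigError("per-pole rates must be non-negative")
        if self.n_generations > 0 and self.rate_old + self.rate_new == 0 and self.n_generations > 1:
            # zero total rate is allowed only for a founders-only simulation
            raise ConfigError(
                "total elongation rate is zero: no cell can ever divide, "
                "so n_generations > 1 is unsatisfiable"
            )
        if not self.division_length > self.birth_length > 0:
            raise ConfigError("require division_length > birth_length > 0")
        if not 0.0 < self.septum_rel_position_mean < 1.0:
            raise ConfigError("septum_rel_position_mean must lie in (0, 1)")
        if self.septum_rel_position_sd < 0:
            raise ConfigError("septum_rel_position_sd must be >= 0")
        if self.rate_cv < 0 or self.pole_share_sd < 0:
            raise ConfigError("rate_cv and pole_share_sd must be >= 0")
        if self.localization_mode not in LOCALIZATION_MODES:
            raise ConfigError(
                f"unknown localization_mode {self.localization_mode!r}; "
                f"expected one of {LOCALIZATION_MODES}"
            )
        for name in ("septal_onset_fraction", "septal_transfer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.pulse_chase_offset_um < 0:
            raise ConfigError("pulse_chase_offset_um must be >= 0")
        if self.label_intensity <= 0:
            raise ConfigError(
                "label_intensity must exceed 0 (label below background makes "
                "the labeled/unlabeled boundary undetectable by construction)"
            )
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.n_founders < 1 or self.n_generations < 1:
            raise ConfigError("n_founders and n_generations must be >= 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
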