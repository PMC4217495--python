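"""Run configuration for the TIRF exocytosis simulator and pipeline.

Two dataclasses carry every tunable of the forward model:

``SimulationConfig``
    Acquisition geometry, event statistics, pharmacological condition and
    camera noise of one simulated movie.

``VesicleKinetics``
    The per-vesicle state machine: pore-opening kinetics, release
    fractions, reacidification and pH-sensor photophysics.

Both round-trip through YAML so that a run is fully reproducible from a
single text file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

CONDITIONS = ("basal", "KCl", "A23187", "bafilomycin", "cycloheximide", "dyngo")

#: (event-count multiplier, persistent-fraction multiplier) per condition.
#: KCl depolarization roughly doubles the event rate and raises the
#: persistent proportion from ~10% to ~22%; the calcium ionophore A23187
#: raises the persistent frequency; bafilomycin leaves frequencies almost
#: unchanged (9.3% vs 9.8%) but switches the vesicle state machine to the
#: no-reacidification mode; cycloheximide and dyngo-4a are no-ops on rates.
CONDITION_MULTIPLIERS: dict[str, tuple[float, float]] = {
    "basal": (1.0, 1.0),
    "KCl": (2.0, 2.24),
    "A23187": (1.5, 1.8),
    "bafilomycin": (1.0, 0.95),
    "cycloheximide": (1.0, 1.0),
    "dyngo": (1.0, 1.0),
}


@dataclass
class VesicleKinetics:
    """Kinetic constants of the vesicle fusion state machine.

    All times are seconds.  Fluorescence of the pH sensor follows a Hill
    sigmoid of lumenal pH with unit slope; reacidification after pore
    closure is modelled as a single exponential in fluorescence with
    half-life ``persistent_decay_halflife_s``.
    """

    transient_release_halflife_s: float = 2.0   # released-pool spot decay
    persistent_decay_halflife_s: float = 17.0   # reacidification (control)
    bafilomycin_fast_halflife_s: float = 2.0    # post-plateau decay
    persistence_dwell_s: float = 8.0            # mean clustered dwell, > 4 s
    partial_release_fraction: float = 0.5       # released at 1st opening of a pair
    reacidification: bool = True                # False under bafilomycin
    pore_reopen_delay_s: float = 8.0            # mean gap before 2nd opening
    pore_open_s: float = 0.3                    # duration the pore stays open
    appear_lead_s: float = 2.0                  # vesicle visible (mCherry) before fusion
    sep_pka: float = 7.1
    ph_open: float = 7.4
    ph_closed: float = 5.5
    surround_gain: float = 0.1                  # sustained surround offset per released unit
    released_offset_halflife_s: float = 25.0    # lateral dispersal of released receptors

    def __post_init__(self) -> None:
        for name in (
            "transient_release_halflife_s",
            "persistent_decay_halflife_s",
            "bafilomycin_fast_halflife_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.partial_release_fraction < 1.0):
            raise ValueError("partial_release_fraction must be in (0, 1)")
        if self.ph_open <= self.ph_closed:
            raise ValueError("ph_open must exceed ph_closed")
        if self.persistence_dwell_s <= 4.0:
            raise ValueError("persistence_dwell_s must be > 4 s")

    def for_condition(self, condition: str) -> "VesicleKinetics":
        """Return a copy adjusted for a pharmacological condition."""
        kin = dataclasses.replace(self)
        if condition == "bafilomycin":
            kin.reacidification = False
        return kin


@dataclass
class SimulationConfig:
    """Acquisition and event statistics of one simulated dual-channel movie."""

    frame_rate_hz: float = 10.0
    duration_s: float = 60.0
    width_px: int = 256
    height_px: int = 256
    pixel_pitch_um: float = 0.16
    mask_spec: Any = "neuron"          # "full", "neuron", {"kind": "neuron", ...}, or array
    n_events: float = 40.0             # expected events per movie
    n_events_exact: bool = False       # Poisson by default
    persistent_fraction: float = 0.098
    consecutive_fraction: float = 0.15
    condition: str = "basal"
    bleach_fraction: float = 0.05      # whole-movie photobleaching loss
    background_level: float = 100.0    # camera background B (counts)
    read_noise_sd: float = 3.0         # Gaussian read noise (counts)
    poisson_gain: float = 1.0          # counts per photoelectron
    psf_sigma_px: float = 1.5
    cargo_mean: float = 500.0          # relative fluorophore units per vesicle
    cargo_sd: float = 75.0
    channels: tuple[str, ...] = ("SEP",)
    n_clathrin_puncta: int = 40        # only used when a "CLC" channel is requested
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")
        if not (0.0 <= self.persistent_fraction <= 1.0):
            raise ValueError("persistent_fraction must be in [0, 1]")
        if not (0.0 <= self.consecutive_fraction <= 1.0):
            raise ValueError("consecutive_fraction must be in [0, 1]")
        if not (0.0 <= self.bleach_fraction < 1.0):
            raise ValueError("bleach_fraction must be in [0, 1)")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        self.channels = tuple(self.channels)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def n_events_effective(self) -> float:
        return self.n_events * CONDITION_MULTIPLIERS[self.condition][0]

    @property
    def persistent_fraction_effective(self) -> float:
        return min(1.0, self.persistent_fraction * CONDITION_MULTIPLIERS[self.condition][1])

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if isinstance(d["mask_spec"], np.ndarray):
            raise ValueError("array mask_spec cannot be serialized; use a file path")
        d["channels"] = list(self.channels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)


def roi_side_px(area_um2: float, pixel_pitch_um: float) -> int:
    """Odd box side (pixels) whose physical side is closest to sqrt(area).

    A 4 um^2 region at 0.16 um/px maps to a 13x13 box and 16 um^2 to 25x25.
    """
    side = np.sqrt(area_um2) / pixel_pitch_um
    odd = int(round((side - 1) / 2)) * 2 + 1
    return max(1, odd)


def colocalization_halfwidth_px(window_um2: float, pixel_pitch_um: float) -> float:
    """Half side length (pixels, possibly fractional) of a physical window."""
    return 0.5 * np.sqrt(window_um2) / pixel_pitch_um
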