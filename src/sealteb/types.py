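"""Core domain containers shared across the pipeline.

A deployment (or captive training session) is represented as a
:class:`SensorTrace` — synchronized channels from a tri-axial
accelerometer, a wet/dry conductivity switch, a pressure (depth) sensor
and a device thermistor — plus :class:`AnimalMeta` describing the animal
carrying the device.  Captive sessions additionally carry a
:class:`LabelTrack` of observer-scored behaviour and location at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The four behaviour categories scored in captive validation sessions.
BEHAVIOURS = ("foraging", "travelling", "grooming", "resting")

#: The three locations a seal can occupy.
LOCATIONS = ("land", "surface", "underwater")

#: Behaviour category -> energetic group (foraging and travelling are
#: costed together as "active").
BEHAVIOUR_GROUPS = {
    "foraging": "active",
    "travelling": "active",
    "grooming": "grooming",
    "resting": "resting",
}

SEASONS = ("winter", "summer")

#: Device dynamic range in g.
ACCEL_RANGE_G = 8.0


@dataclass
class AnimalMeta:
    """Per-animal metadata carried as model covariates."""

    mass_kg: float = 30.0
    sex: str = "F"
    age_class: str = "juvenile"
    species: str = "Arctocephalus pusillus"
    attachment: str = "tape"
    season: str = "winter"
    colony: str = ""

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError(f"mass_kg must be positive, got {self.mass_kg}")
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age_class not in ("juvenile", "adult"):
            raise ValueError(f"age_class must be juvenile/adult, got {self.age_class!r}")
        if self.attachment not in ("harness", "tape"):
            raise ValueError(f"attachment must be harness/tape, got {self.attachment!r}")


@dataclass
class SensorTrace:
    """Synchronized multi-channel record for one deployment or session.

    Attributes
    ----------
    accel : (n, 3) float array
        Tri-axial acceleration in g at ``rate_hz``, clipped to the
        device range of +/- 8 g.
    wet : (n_s,) bool array
        Wet/dry switch at 1 Hz (True = in water).
    depth : (n_s,) float array
        Depth in metres at 1 Hz, non-negative after zero-offset
        correction; 0 whenever the animal is dry.
    temperature : (n_s // 2,) float array
        Device temperature in deg C at 0.5 Hz.
    rate_hz : int
        Acceleration sampling rate, 1 or 20.
    bursts : list of SensorTrace, optional
        High-resolution (20 Hz) burst segments triggered by diving,
        when requested from the wild generator.
    """

    accel: np.ndarray
    wet: np.ndarray
    depth: np.ndarray
    temperature: np.ndarray
    rate_hz: int
    animal: AnimalMeta = field(default_factory=AnimalMeta)
    start_s: float = 0.0
    bursts: Optional[list] = None

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.wet = np.asarray(self.wet, dtype=bool)
        self.depth = np.asarray(self.depth, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.rate_hz not in (1, 20):
            raise ValueError(f"rate_hz must be 1 or 20, got {self.rate_hz}")
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must be an (n, 3) array")
        n_s = len(self.wet)
        if len(self.depth) != n_s:
            raise ValueError("wet and depth must both be 1 Hz series of equal length")
        if len(self.accel) != n_s * self.rate_hz:
            raise ValueError(
                f"accel length {len(self.accel)} inconsistent with "
                f"{n_s} s at {self.rate_hz} Hz"
            )

    @property
    def duration_s(self) -> int:
        return len(self.wet)

    @property
    def times_s(self) -> np.ndarray:
        """Acceleration sample times in seconds from the trace start."""
        return self.start_s + np.arange(len(self.accel)) / self.rate_hz


@dataclass
class LabelTrack:
    """Per-second observer labels for a captive session."""

    behaviour: np.ndarray  # str per second, from BEHAVIOURS
    location: np.ndarray  # str per second, from LOCATIONS

    def __post_init__(self) -> None:
        self.behaviour = np.asarray(self.behaviour, dtype=object)
        self.location = np.asarray(self.location, dtype=object)
        if len(self.behaviour) != len(self.location):
            raise ValueError("behaviour and location tracks must have equal length")
        bad_b = set(self.behaviour) - set(BEHAVIOURS)
        if bad_b:
            raise ValueError(f"unknown behaviour labels: {sorted(bad_b)}")
        bad_l = set(self.location) - set(LOCATIONS)
        if bad_l:
            raise ValueError(f"unknown location labels: {sorted(bad_l)}")

    def __len__(self) -> int:
        return len(self.behaviour)
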