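"""Shared domain containers for the NBHF click-analysis pipeline.

Conventions used throughout the package:

* pressures are calibrated in µPa; levels in dB re 1 µPa (pp / rms) or
  dB re 1 µPa²s (energy flux density);
* coordinates are right-handed with z positive *downward* from the sea
  surface and the hydrophone array on the z-axis;
* frequencies are given in kHz at API boundaries unless a field name says
  otherwise (sample rates are always Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidParameterError(ValueError):
    """A physically meaningless or out-of-contract parameter value."""


@dataclass
class EnvironmentProfile:
    """Water-column properties controlling sound speed and absorption.

    Parameters
    ----------
    temperature : float
        Water temperature, °C.
    salinity : float
        Salinity, parts per thousand (‰).
    depth : float
        Nominal recording depth, m.
    sound_speed : float, optional
        Fixed sound speed, m/s.  When ``None`` the Mackenzie (1981)
        nine-term formula is evaluated on demand.
    ph : float
        pH, needed by the boric-acid relaxation term of the absorption
        models.  Default 8.0.
    """

    temperature: float
    salinity: float
    depth: float = 5.0
    sound_speed: float | None = None
    ph: float = 8.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise InvalidParameterError(
                f"temperature {self.temperature} °C outside [-2, 40]"
            )
        if not (0.0 <= self.salinity <= 45.0):
            raise InvalidParameterError(f"salinity {self.salinity} ‰ outside [0, 45]")
        if self.depth < 0:
            raise InvalidParameterError("depth must be non-negative")

    def c(self) -> float:
        """Sound speed in m/s (fixed value or derived from T/S/depth)."""
        if self.sound_speed is not None:
            return float(self.sound_speed)
        from . import source_level

        return source_level.sound_speed(self)


#: spacings of the six-element vertical array: 1.5 m between the two topmost
#: hydrophones, 0.75 m between all others (top hydrophone at ``top_depth``).
DEFAULT_SPACINGS = (1.5, 0.75, 0.75, 0.75, 0.75)


@dataclass
class ArrayGeometry:
    """Hydrophone positions for a (nominally vertical, linear) array.

    ``positions`` is an (n, 3) array of [x, y, z] in metres, z positive
    downward.  ``reference_channel`` anchors TDOAs and localization ranges.
    """

    positions: np.ndarray
    active_channels: tuple[int, ...] | None = None
    reference_channel: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 3:
            raise InvalidParameterError("positions must be (n, 3)")
        if self.active_channels is None:
            self.active_channels = tuple(range(self.n_channels))
        else:
            self.active_channels = tuple(int(c) for c in self.active_channels)
        if len(self.active_channels) < 4:
            raise InvalidParameterError(
                "at least 4 active channels are required for 3-D localization"
            )
        act = self.positions[list(self.active_channels)]
        if len(np.unique(act.round(9), axis=0)) != len(act):
            raise InvalidParameterError("hydrophone positions must be distinct")
        if self.reference_channel not in self.active_channels:
            raise InvalidParameterError("reference channel must be active")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def default_vertical(
        cls,
        top_depth: float = 2.0,
        spacings: tuple[float, ...] = DEFAULT_SPACINGS,
        active_channels: tuple[int, ...] | None = None,
        reference_channel: int = 0,
    ) -> "ArrayGeometry":
        """Six-element vertical line array on the z-axis.

        Default depths (top at 2 m) give hydrophones at 2.0, 3.5, 4.25,
        5.0, 5.75 and 6.5 m, i.e. 0.75 m spacing with a 1.5 m gap between
        the two topmost elements.
        """
        z = top_depth + np.concatenate([[0.0], np.cumsum(spacings)])
        pos = np.zeros((len(z), 3))
        pos[:, 2] = z
        return cls(pos, active_channels=active_channels,
                   reference_channel=reference_channel)


@dataclass
class ClickWaveform:
    """A calibrated single-channel pressure snippet.

    ``samples`` are instantaneous pressures in µPa (or a unit-peak template
    before scaling), ``time_offset`` places the first sample on the
    recording's absolute time axis in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    channel_id: int = 0
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.time_offset + np.arange(self.samples.size) / self.sample_rate

    def scaled(self, factor: float) -> "ClickWaveform":
        return ClickWaveform(self.samples * factor, self.sample_rate,
                             self.channel_id, self.time_offset)


@dataclass
class ArrayRecording:
    """Time-synchronous multichannel recording plus metadata.

    ``samples`` is (n_channels, n_samples) in calibrated µPa.
    ``ground_truth`` carries the simulator's sidecar (true positions,
    emitted parameters, on-axis channel) when the recording is synthetic.
    """

    samples: np.ndarray
    sample_rate: float
    geometry: ArrayGeometry
    environment: EnvironmentProfile
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != self.geometry.n_channels:
            raise InvalidParameterError(
                f"recording has {self.samples.shape[0]} channels but geometry "
                f"defines {self.geometry.n_channels}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate


def db(x: np.ndarray | float) -> np.ndarray | float:
    """20·log10 of a pressure ratio (amplitude to dB)."""
    return 20.0 * np.log10(x)


def db_power(x: np.ndarray | float) -> np.ndarray | float:
    """10·log10 of a power/energy ratio."""
    return 10.0 * np.log10(x)
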