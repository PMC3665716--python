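"""Active sonar-equation model of NBHF versus broadband click detection.

The echo-to-noise ratio of an echolocation click of centroid frequency
f_c and rms bandwidth BW at target range r is

    ENR(r) = SL − 2·TL(r) + TS − NL(f_c, BW) + DI − DT,
    TL(r)  = 20·log10(r) + α(f_c)·r,
    NL     = N₀(f_c) + 10·log10(BW),

with source energy flux density SL, target strength TS, receiving
directivity DI and detection threshold DT held fixed across compared
scenarios.  Everything fixed cancels when ENR is normalized to a
reference scenario (the 130 kHz / 15 kHz NBHF click), leaving

    ΔENR(r) = −2r·[α(f_c) − α(f_ref)] − [N₀(f_c) − N₀(f_ref)]
              − 10·log10(BW / BW_ref)

— an absorption term, a noise-window term and a bandwidth term.  The
ambient spectral level N₀ is a committed parametric deep-water fixture
(sea-state wind noise decaying 17 dB/decade plus thermal noise rising
20 dB/decade), replaceable by any two-column CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import EnvironmentProfile, InvalidParameterError
from .source_level import absorption_coefficient

__all__ = [
    "NoiseModel",
    "SonarScenario",
    "DetectionCurve",
    "noise_level",
    "delta_enr_curve",
    "crossover_ranges",
    "efd_pp_equivalence",
    "MODEL_ENVIRONMENT",
    "REFERENCE_SCENARIO",
    "MODEL_FREQUENCIES_KHZ",
    "NBHF_BW_KHZ",
    "BROADBAND_BW_KHZ",
]

#: model environment (14 °C, 33 ‰) — distinct from the field-site profiles
MODEL_ENVIRONMENT = EnvironmentProfile(temperature=14.0, salinity=33.0, depth=5.0)

#: the centroid frequencies and bandwidths compared by the model
MODEL_FREQUENCIES_KHZ = (32.5, 65.0, 130.0, 200.0)
NBHF_BW_KHZ = 15.0
BROADBAND_BW_KHZ = 45.0

_NOISE_SUPPORT_KHZ = (10.0, 250.0)


@dataclass
class NoiseModel:
    """Ambient spectral noise level N₀(f), dB re 1 µPa²/Hz.

    Piecewise-linear interpolation over a tabulated spectrum.  The
    default table (packaged CSV) is a deep-water parametric stand-in:
    a sea-state wind term falling 17 dB/decade plus thermal noise rising
    20 dB/decade, which places the low-noise window near 100–150 kHz.
    """

    frequencies_khz: np.ndarray
    levels_db: np.ndarray
    name: str = "noise"
    sea_state: int | None = None

    def __post_init__(self) -> None:
        self.frequencies_khz = np.asarray(self.frequencies_khz, float)
        self.levels_db = np.asarray(self.levels_db, float)
        if np.any(np.diff(self.frequencies_khz) <= 0):
            raise InvalidParameterError("noise table frequencies must increase")
        if not np.all(np.isfinite(self.levels_db)):
            raise InvalidParameterError("noise levels must be finite")

    def spectral_level(self, f_khz: float | np.ndarray) -> float | np.ndarray:
        f = np.asarray(f_khz, float)
        lo, hi = self.frequencies_khz[0], self.frequencies_khz[-1]
        if np.any(f < lo) or np.any(f > hi):
            raise InvalidParameterError(
                f"frequency outside noise-model support [{lo}, {hi}] kHz"
            )
        out = np.interp(f, self.frequencies_khz, self.levels_db)
        return float(out) if np.isscalar(f_khz) else out

    @staticmethod
    def parametric(
        f_khz: np.ndarray,
        sea_state: int = 3,
        wind_level_at_1khz_db: float = 60.0,
        wind_slope_db_per_decade: float = -17.0,
        thermal_offset_db: float = -15.0,
    ) -> np.ndarray:
        """Wind/sea-state plus thermal spectral levels, dB re 1 µPa²/Hz.

        The wind term is anchored at 1 kHz (Knudsen-style, sea state 3 by
        default, +5 dB per sea state step) and decays 17 dB/decade; the
        thermal term is −15 + 20·log10(f kHz).
        """
        f = np.asarray(f_khz, float)
        wind0 = wind_level_at_1khz_db + 5.0 * (sea_state - 3)
        wind = wind0 + wind_slope_db_per_decade * np.log10(f)
        thermal = thermal_offset_db + 20.0 * np.log10(f)
        return 10.0 * np.log10(10.0 ** (wind / 10.0) + 10.0 ** (thermal / 10.0))

    @classmethod
    def default(cls) -> "NoiseModel":
        """The committed deep-water sea-state-3 fixture table."""
        with resources.files("nbhfsonar.data").joinpath(
            "noise_deep_water_ss3.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
        return cls(df["frequency_khz"].to_numpy(), df["level_db"].to_numpy(),
                   name="deep_water_ss3", sea_state=3)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "NoiseModel":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   name=name or str(path))


@dataclass
class SonarScenario:
    """One click type in the detection-range comparison.

    The absolute source EFD, target strength, receive DI and detection
    threshold are shared constants across compared scenarios; since all
    outputs are ΔENR-normalized they never need numeric values.
    """

    fc_khz: float
    bw_rms_khz: float
    environment: EnvironmentProfile = field(default_factory=lambda: MODEL_ENVIRONMENT)
    absorption_formulation: str = "fisher_simmons"
    label: str = ""

    def __post_init__(self) -> None:
        if self.bw_rms_khz <= 0:
            raise InvalidParameterError("bandwidth must be positive")
        if not self.label:
            self.label = f"{self.fc_khz:g}kHz/{self.bw_rms_khz:g}kHz"

    def alpha_db_per_m(self) -> float:
        return absorption_coefficient(
            self.fc_khz, self.environment, self.absorption_formulation
        )


REFERENCE_SCENARIO = SonarScenario(fc_khz=130.0, bw_rms_khz=NBHF_BW_KHZ,
                                   label="NBHF 130kHz/15kHz")


@dataclass
class DetectionCurve:
    ranges_m: np.ndarray
    delta_enr_db: np.ndarray
    scenario: SonarScenario
    terms: dict[str, np.ndarray | float] = field(default_factory=dict)


def noise_level(fc_khz: float, bw_rms_khz: float, nm: NoiseModel) -> float:
    """Masking noise NL = N₀(f_c) + 10·log10(BW), BW in Hz."""
    if bw_rms_khz <= 0:
        raise InvalidParameterError("bandwidth must be positive")
    return float(nm.spectral_level(fc_khz) + 10.0 * np.log10(bw_rms_khz * 1e3))


def delta_enr_curve(
    scenario: SonarScenario,
    reference: SonarScenario,
    ranges_m: np.ndarray,
    nm: NoiseModel | None = None,
) -> DetectionCurve:
    """ΔENR(r) of a scenario relative to the reference at the same range.

    Spreading terms cancel by construction; the curve decomposes exactly
    into absorption, noise-window and bandwidth terms (stored in
    ``terms``).
    """
    if scenario.environment != reference.environment or (
        scenario.absorption_formulation != reference.absorption_formulation
    ):
        raise InvalidParameterError(
            "scenario and reference must share environment and absorption "
            "formulation (fixed-field contract)"
        )
    nm = nm or NoiseModel.default()
    r = np.asarray(ranges_m, float)
    d_alpha = scenario.alpha_db_per_m() - reference.alpha_db_per_m()
    absorption_term = -2.0 * r * d_alpha
    noise_term = -(nm.spectral_level(scenario.fc_khz)
                   - nm.spectral_level(reference.fc_khz))
    bw_term = -10.0 * np.log10(scenario.bw_rms_khz / reference.bw_rms_khz)
    delta = absorption_term + noise_term + bw_term
    return DetectionCurve(
        ranges_m=r,
        delta_enr_db=delta,
        scenario=scenario,
        terms={
            "absorption_db": absorption_term,
            "noise_window_db": noise_term,
            "bandwidth_db": bw_term,
        },
    )


def crossover_ranges(curves: list[DetectionCurve]) -> dict[str, float | None]:
    """First range where each ΔENR curve crosses 0 (linear interpolation).

    Returns None for a curve that never crosses within its range grid,
    including the identically-zero reference curve.
    """
    out: dict[str, float | None] = {}
    for curve in curves:
        y = curve.delta_enr_db
        r = curve.ranges_m
        if np.allclose(y, 0.0):
            out[curve.scenario.label] = None
            continue
        sign = np.sign(y)
        flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
        exact = np.flatnonzero(y == 0.0)
        candidates = []
        for i in flips:
            frac = y[i] / (y[i] - y[i + 1])
            candidates.append(r[i] + frac * (r[i + 1] - r[i]))
        candidates.extend(r[exact])
        out[curve.scenario.label] = float(min(candidates)) if candidates else None
    return out


def plot_detection_curves(curves: list[DetectionCurve], path=None):
    """ΔENR versus target range: solid lines for 15 kHz bandwidth
    scenarios, broken lines for 45 kHz; saved to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for curve in curves:
        style = "-" if curve.scenario.bw_rms_khz <= NBHF_BW_KHZ else "--"
        ax.plot(curve.ranges_m, curve.delta_enr_db, style,
                label=curve.scenario.label)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("target range (m)")
    ax.set_ylabel("ΔENR re NBHF reference (dB)")
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def efd_pp_equivalence(
    duration_a_us: float, sl_pp_a_db: float, duration_b_us: float
) -> float:
    """Peak-peak source level giving click b the same energy flux density
    as click a, assuming identical envelope shapes.

    A longer click carries proportionally more energy at the same peak
    pressure, so sl_pp_b = sl_pp_a + 10·log10(d_a / d_b); e.g. a 25 µs
    dolphin-style click needs 206 dB pp to match a 100 µs NBHF click at
    200 dB pp.
    """
    if duration_a_us <= 0 or duration_b_us <= 0:
        raise InvalidParameterError("durations must be positive")
    return sl_pp_a_db + 10.0 * np.log10(duration_a_us / duration_b_us)
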