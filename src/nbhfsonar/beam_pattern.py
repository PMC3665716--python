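"""Vertical beam pattern, piston fit, equivalent aperture and directivity.

When an on-axis click is received simultaneously on all hydrophones, the
angles from the animal's acoustic axis to the five off-axis hydrophones
are known from the localization, and the received levels at those angles
sample the transmission beam.  Pooling samples across accepted clicks
recorded within 20 m of the array yields a composite vertical beam
pattern, which is fitted by the far-field directivity of a circular
piston of radius a,

    b(θ) = 2·J1(k·a·sinθ) / (k·a·sinθ),   k = 2πf/c at the centroid frequency.

The fitted *equivalent aperture* is the piston diameter 2a; the
directivity index follows from the fitted beam under the assumption of
rotational symmetry,

    DI = 10·log10( 2 / ∫₀^π b²(θ)·sinθ dθ ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import ArrayGeometry, InvalidParameterError
from .source_level import transmission_loss

__all__ = [
    "BeamSample",
    "PistonFit",
    "compute_offaxis_angles",
    "build_composite_beam",
    "fit_piston_beam",
    "piston_beam_db",
    "directivity_index",
    "FIRST_BESSEL_NULL",
    "BEAM_MAX_RANGE_M",
    "BEAM_DYNAMIC_RANGE_DB",
]

#: first root of J1: the piston main-lobe null is at k·a·sinθ = 3.8317
FIRST_BESSEL_NULL = 3.8317059702075125

#: beam patterns are built only from clicks recorded within 20 m
BEAM_MAX_RANGE_M = 20.0

#: samples below this level re on-axis are dropped (display/noise floor of
#: composite beam patterns; field samples this far down are noise-dominated)
BEAM_DYNAMIC_RANGE_DB = -30.0


@dataclass
class BeamSample:
    angle_deg: float
    relative_level_db: float  # re on-axis
    click_id: int = 0
    channel_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg <= 90.0):
            raise InvalidParameterError("angle must be in [0, 90] degrees")


@dataclass
class PistonFit:
    equivalent_aperture_cm: float
    directivity_index_db: float
    fit_rss_db2: float
    ka: float


def compute_offaxis_angles(
    source_position: np.ndarray,
    geometry: ArrayGeometry,
    onaxis_channel: int,
) -> dict[int, float]:
    """Angle (degrees) between the source→on-axis-hydrophone ray and the
    source→hydrophone ray, per active channel.

    The acoustic axis of an accepted on-axis click is taken to point at
    the on-axis hydrophone.
    """
    pos = np.asarray(source_position, float)
    if not np.all(np.isfinite(pos)):
        raise InvalidParameterError("source position unavailable")
    axis = geometry.positions[onaxis_channel] - pos
    axis = axis / np.linalg.norm(axis)
    angles: dict[int, float] = {}
    for ch in geometry.active_channels:
        v = geometry.positions[ch] - pos
        v = v / np.linalg.norm(v)
        angles[ch] = math.degrees(math.acos(float(np.clip(np.dot(axis, v), -1, 1))))
    return angles


def build_composite_beam(
    accepted_clicks: list[dict],
    geometry: ArrayGeometry,
    alpha_db_per_m: float,
    max_range_m: float = BEAM_MAX_RANGE_M,
    dynamic_range_db: float = BEAM_DYNAMIC_RANGE_DB,
) -> list[BeamSample]:
    """Pool range-normalized off-axis levels across accepted clicks.

    Each element of ``accepted_clicks`` is a dict with keys ``position``
    (3-vector), ``onaxis_channel`` (int), ``levels_db`` (per-channel
    received pp levels) and ``click_id``.  Every channel's level is first
    corrected by its own transmission loss (the hydrophones sit at
    different ranges), then expressed relative to the on-axis channel.
    Clicks localized beyond ``max_range_m`` are excluded; samples below
    ``dynamic_range_db`` re on-axis are dropped.
    """
    samples: list[BeamSample] = []
    for click in accepted_clicks:
        pos = np.asarray(click["position"], float)
        on_ch = int(click["onaxis_channel"])
        r_on = float(np.linalg.norm(pos - geometry.positions[on_ch]))
        if r_on > max_range_m:
            continue
        angles = compute_offaxis_angles(pos, geometry, on_ch)
        levels = click["levels_db"]
        norm = {
            ch: levels[ch] + transmission_loss(
                float(np.linalg.norm(pos - geometry.positions[ch])),
                alpha_db_per_m)
            for ch in levels
        }
        ref = norm[on_ch]
        for ch, lvl in norm.items():
            rel = lvl - ref
            if rel < dynamic_range_db:
                continue
            samples.append(BeamSample(angles[ch], rel,
                                      click_id=click.get("click_id", 0),
                                      channel_id=ch))
    return samples


def piston_beam_db(angle_deg: np.ndarray, ka: float,
                   floor_db: float = -60.0) -> np.ndarray:
    """20·log10 |2·J1(x)/x| with x = ka·sinθ, floored for numerical safety."""
    from scipy.special import j1

    x = ka * np.sin(np.radians(np.asarray(angle_deg, float)))
    b = np.ones_like(x)
    nz = x != 0
    b[nz] = 2.0 * j1(x[nz]) / x[nz]
    return 20.0 * np.log10(np.maximum(np.abs(b), 10.0 ** (floor_db / 20.0)))


def directivity_index(ka: float, n_grid: int = 20001) -> float:
    """DI of the rotationally symmetric piston beam by numerical quadrature.

    DI = 10·log10(2 / ∫₀^π b²(θ) sinθ dθ), trapezoid rule on a fine grid.
    """
    theta = np.linspace(0.0, np.pi, n_grid)
    from scipy.special import j1

    x = ka * np.sin(theta)
    b = np.ones_like(x)
    nz = x != 0
    b[nz] = 2.0 * j1(x[nz]) / x[nz]
    integral = np.trapezoid(b**2 * np.sin(theta), theta)
    return float(10.0 * np.log10(2.0 / integral))


def plot_beam(
    samples: list[BeamSample],
    fit: PistonFit | None = None,
    path=None,
    title: str = "Vertical beam pattern",
):
    """Polar plot of beam samples (0–90° off-axis, 0 to −30 dB re on-axis),
    optionally with the fitted piston curve; saved to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_thetamin(0)
    ax.set_thetamax(90)
    ax.set_rlim(-30.0, 0.0)
    ax.plot(np.radians([s.angle_deg for s in samples]),
            [s.relative_level_db for s in samples], "ko", ms=4,
            label="samples")
    if fit is not None:
        theta = np.linspace(0.0, 90.0, 400)
        ax.plot(np.radians(theta), np.maximum(
            piston_beam_db(theta, fit.ka), -30.0), "r-",
            label=f"piston {fit.equivalent_aperture_cm:.1f} cm, "
                  f"DI {fit.directivity_index_db:.1f} dB")
    ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def fit_piston_beam(
    samples: list[BeamSample],
    fc_khz: float,
    sound_speed: float,
    sidelobe_weight: float = 0.5,
) -> PistonFit:
    """Least-squares piston fit to composite beam samples.

    Fits the aperture radius plus a free dB gain by minimizing dB
    residuals of 20·log10|2J1(ka·sinθ)/(ka·sinθ)|; the gain absorbs any
    uniform offset of the samples so only the beam *shape* determines the
    aperture and DI.  Samples beyond the first Bessel null are
    down-weighted (near-null field samples are noise-dominated).
    Returns the equivalent aperture diameter, the directivity index of
    the fitted beam and the residual sum of squares.
    """
    if len(samples) < 5:
        raise InvalidParameterError("need at least 5 beam samples")
    angles = np.array([s.angle_deg for s in samples])
    if np.unique(np.round(angles, 3)).size < 3:
        raise InvalidParameterError("need samples at >= 3 distinct angles")
    levels = np.array([s.relative_level_db for s in samples])
    k = 2.0 * np.pi * fc_khz * 1e3 / sound_speed

    def resid(p):
        ka = k * math.exp(p[0])  # p = (log(a), gain_db)
        w = np.where(ka * np.sin(np.radians(angles)) > FIRST_BESSEL_NULL,
                     sidelobe_weight, 1.0)
        return w * (piston_beam_db(angles, ka) + p[1] - levels)

    best = None
    for a0_cm in (2.0, 5.0, 7.5, 10.0, 15.0, 20.0):
        sol = least_squares(resid, [math.log(a0_cm / 200.0), 0.0], xtol=1e-12,
                            ftol=1e-12, max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e3:
        raise RuntimeError("piston fit failed to converge")
    a = math.exp(best.x[0])
    ka = k * a
    return PistonFit(
        equivalent_aperture_cm=2.0 * a * 100.0,
        directivity_index_db=directivity_index(ka),
        fit_rss_db2=float(2.0 * best.cost),
        ka=ka,
    )
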