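"""Click source parameters from a single calibrated click snippet.

Eleven parameters characterize each on-axis click:

time domain (from the Hilbert envelope)
    * -10 dB duration (µs), between the first and last crossings of the
      envelope peak minus 10 dB;
    * received level peak-peak, rms and energy flux density — the rms and
      EFD integrals are taken over the -10 dB duration window only.

frequency domain (512-point rectangular-window FFT, spectrum interpolated
by zero-padding ×10, click envelope peak centered in the window)
    * peak frequency (spectral arg-max);
    * centroid frequency, defined as the frequency dividing the power
      spectrum into two halves of equal energy (an energy-weighted *mean*
      variant is available behind a flag);
    * -3 dB and -10 dB bandwidths about the spectral peak;
    * rms bandwidth — the energy-weighted spectral standard deviation
      about the centroid frequency on a linear scale;
    * Q_rms = Fc / BW_rms and Q_-3dB = Fpeak / BW_-3dB.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import hilbert

from .core import ClickWaveform, InvalidParameterError, db, db_power

__all__ = [
    "ClickParameters",
    "compute_envelope_metrics",
    "compute_spectral_metrics",
    "measure_click",
    "TruncatedClickError",
    "WindowTooShortError",
]


class TruncatedClickError(ValueError):
    """The click envelope peaks at the snippet edge; metrics undefined."""


class WindowTooShortError(ValueError):
    """The click does not fit in the requested analysis window."""


@dataclass
class ClickParameters:
    duration_10db: float  # µs
    f_peak: float         # kHz
    f_centroid: float     # kHz
    bw_3db: float         # kHz
    bw_10db: float        # kHz
    bw_rms: float         # kHz
    q_rms: float
    q_3db: float
    rl_pp: float          # dB re 1 µPa pp
    rl_rms: float         # dB re 1 µPa rms
    rl_efd: float         # dB re 1 µPa²s

    #: CSV column names, ASCII-normalized from the conventional table headers
    TABLE_COLUMNS = {
        "duration_10db": "10dB duration, us",
        "rl_pp": "Level, dB re 1 uPa (p.-p.)",
        "rl_rms": "Level_-10db, dB re 1 uPa (rms)",
        "rl_efd": "Energy flux density_-10db, dB re 1 uPa^2 s",
        "f_peak": "Peak frequency, kHz",
        "f_centroid": "Centroid frequency, kHz",
        "bw_3db": "3dB bandwidth, kHz",
        "bw_10db": "10dB bandwidth, kHz",
        "bw_rms": "RMS bandwidth, kHz",
        "q_3db": "Q_-3dB",
        "q_rms": "Q_RMS",
    }

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _envelope(samples: np.ndarray) -> np.ndarray:
    return np.abs(hilbert(samples))


def compute_envelope_metrics(
    w: ClickWaveform,
) -> tuple[float, float, float, float]:
    """(-10 dB duration µs, RL_pp, RL_rms, RL_efd) from the signal envelope.

    The envelope is the magnitude of the analytic signal; the duration is
    the span between the first and last crossings of (peak - 10 dB), with
    linear sub-sample interpolation at the crossings.  rms and EFD levels
    are integrated over that window only.
    """
    x = w.samples
    if x.size < 8:
        raise TruncatedClickError("snippet too short to carry a click")
    env = _envelope(x)
    ipk = int(np.argmax(env))
    if ipk == 0 or ipk == env.size - 1:
        raise TruncatedClickError("envelope peak at snippet edge")
    thresh = env[ipk] * 10.0 ** (-10.0 / 20.0)
    if env[0] >= thresh or env[-1] >= thresh:
        raise TruncatedClickError(
            "snippet does not contain the full -10 dB envelope"
        )

    above = env >= thresh
    idx = np.flatnonzero(above)
    first, last = idx[0], idx[-1]
    # sub-sample crossing positions (samples)
    if first > 0:
        frac = (thresh - env[first - 1]) / (env[first] - env[first - 1])
        t0 = first - 1 + frac
    else:
        t0 = 0.0
    if last < env.size - 1:
        frac = (env[last] - thresh) / (env[last] - env[last + 1])
        t1 = last + frac
    else:
        t1 = float(env.size - 1)
    duration_us = (t1 - t0) / w.sample_rate * 1e6

    rl_pp = db(np.max(x) - np.min(x))
    win = x[first : last + 1]
    dur_s = (t1 - t0) / w.sample_rate
    energy = np.sum(win**2) / w.sample_rate  # µPa²·s
    rl_rms = db_power(energy / dur_s)
    rl_efd = db_power(energy)
    return float(duration_us), float(rl_pp), float(rl_rms), float(rl_efd)


def _windowed_spectrum(
    w: ClickWaveform, nfft: int, interp_factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of the click centered in an nfft rectangular window,
    zero-padded by ``interp_factor`` before the transform.

    Returns (frequencies kHz, power spectrum, linear units).
    """
    x = w.samples
    env = _envelope(x)
    ipk = int(np.argmax(env))
    # the -10 dB extent must fit inside the window
    thresh = env[ipk] * 10.0 ** (-0.5)
    idx = np.flatnonzero(env >= thresh)
    if (idx[-1] - idx[0]) >= nfft:
        raise WindowTooShortError(
            f"click -10 dB extent {idx[-1] - idx[0]} samples exceeds the "
            f"{nfft}-point analysis window"
        )
    half = nfft // 2
    seg = np.zeros(nfft)
    lo = max(0, ipk - half)
    hi = min(x.size, lo + nfft)
    lo = max(0, hi - nfft)
    off = half - (ipk - lo)
    off = max(0, min(off, nfft - (hi - lo)))
    seg[off : off + (hi - lo)] = x[lo:hi]

    spec = np.fft.rfft(seg, n=nfft * interp_factor)
    freqs = np.fft.rfftfreq(nfft * interp_factor, d=1.0 / w.sample_rate) / 1e3
    return freqs, np.abs(spec) ** 2


def _median_energy_frequency(freqs: np.ndarray, p: np.ndarray) -> float:
    """Frequency splitting the cumulative spectral energy into equal halves,
    with linear interpolation inside the straddling bin."""
    cum = np.cumsum(p)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(freqs[0])
    prev = cum[i - 1]
    frac = (half - prev) / (cum[i] - prev)
    return float(freqs[i - 1] + frac * (freqs[i] - freqs[i - 1]))


def _bandwidth_about_peak(
    freqs: np.ndarray, p: np.ndarray, drop_db: float
) -> float:
    """Width (kHz) of the contiguous region around the global spectral peak
    above (peak - drop_db), with sub-bin interpolation at the edges."""
    ipk = int(np.argmax(p))
    thresh = p[ipk] * 10.0 ** (-drop_db / 10.0)
    lo = ipk
    while lo > 0 and p[lo - 1] >= thresh:
        lo -= 1
    hi = ipk
    while hi < p.size - 1 and p[hi + 1] >= thresh:
        hi += 1
    f_lo = freqs[lo]
    if lo > 0:
        frac = (p[lo] - thresh) / (p[lo] - p[lo - 1])
        f_lo = freqs[lo] - frac * (freqs[lo] - freqs[lo - 1])
    f_hi = freqs[hi]
    if hi < p.size - 1:
        frac = (p[hi] - thresh) / (p[hi] - p[hi + 1])
        f_hi = freqs[hi] + frac * (freqs[hi + 1] - freqs[hi])
    return float(f_hi - f_lo)


def compute_spectral_metrics(
    w: ClickWaveform,
    nfft: int = 512,
    interp_factor: int = 10,
    centroid: str = "median",
) -> tuple[float, float, float, float, float, float, float]:
    """(f_peak, f_centroid, bw_3db, bw_10db, bw_rms, q_rms, q_3db), all kHz.

    ``centroid='median'`` (default) uses the equal-energy-halves frequency;
    ``centroid='mean'`` the conventional energy-weighted mean frequency.
    The rms bandwidth is always the energy-weighted standard deviation
    about the *median* or *mean* centroid per the selected definition.
    """
    if interp_factor < 1:
        raise InvalidParameterError("interp_factor must be >= 1")
    if centroid not in ("median", "mean"):
        raise InvalidParameterError("centroid must be 'median' or 'mean'")
    freqs, p = _windowed_spectrum(w, nfft, interp_factor)

    f_peak = float(freqs[np.argmax(p)])
    if centroid == "median":
        f_c = _median_energy_frequency(freqs, p)
    else:
        f_c = float(np.sum(freqs * p) / np.sum(p))
    bw_rms = float(np.sqrt(np.sum(p * (freqs - f_c) ** 2) / np.sum(p)))
    bw_3 = _bandwidth_about_peak(freqs, p, 3.0)
    bw_10 = _bandwidth_about_peak(freqs, p, 10.0)
    q_rms = f_c / bw_rms
    q_3 = f_peak / bw_3
    return f_peak, f_c, bw_3, bw_10, bw_rms, q_rms, q_3


def measure_click(
    w: ClickWaveform,
    nfft: int = 512,
    interp_factor: int = 10,
    centroid: str = "median",
) -> ClickParameters:
    """All eleven click source parameters for one snippet."""
    dur, rl_pp, rl_rms, rl_efd = compute_envelope_metrics(w)
    f_peak, f_c, bw3, bw10, bw_rms, q_rms, q3 = compute_spectral_metrics(
        w, nfft=nfft, interp_factor=interp_factor, centroid=centroid
    )
    return ClickParameters(
        duration_10db=dur,
        f_peak=f_peak,
        f_centroid=f_c,
        bw_3db=bw3,
        bw_10db=bw10,
        bw_rms=bw_rms,
        q_rms=q_rms,
        q_3db=q3,
        rl_pp=rl_pp,
        rl_rms=rl_rms,
        rl_efd=rl_efd,
    )
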