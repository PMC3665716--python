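"""Click detection, scan grouping, TDOA estimation, localization and
on-axis selection for the six-element vertical array.

A *scan* is a series of clicks closely spaced in time whose received
levels vary rapidly as the animal sweeps its narrow beam across the
array.  At most one click per scan is accepted as on-axis, by six
criteria: the click must (i) be recorded on all six (five) channels,
(ii) be part of a scan, (iii) be the strongest click of the scan,
(iv) peak on one of the four (three) middle hydrophones, (v) have its
direct path stronger than any trailing surface/bottom reflection, and
(vi) be the only accepted click of its scan.  Buzz clicks (inter-click
intervals below ~13 ms, i.e. repetition rates of some hundred clicks
per second) are excluded before selection.

Localization uses the over-determined TDOA set: a Gauss–Newton
least-squares fit (multi-start) of a source position in the
(horizontal range, depth) plane — the line array cannot resolve
azimuth — plus a leave-one-hydrophone-out spread of the implied
transmission loss as the localization quality measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, hilbert

from .core import ArrayGeometry, ArrayRecording, ClickWaveform, InvalidParameterError

__all__ = [
    "ClickEvent",
    "ScanSegment",
    "LocalizationResult",
    "OnAxisDecision",
    "DetectorSettings",
    "detect_and_segment",
    "estimate_tdoas",
    "localize",
    "select_on_axis",
    "LocalizationError",
]

#: default analysis settings (the field study did not publish detector
#: internals; these are package choices, see docs/methods.md)
DEFAULT_SCAN_GAP_MS = 300.0
DEFAULT_BUZZ_ICI_MS = 13.0
DEFAULT_ECHO_WINDOW_MS = 20.0


class LocalizationError(RuntimeError):
    pass


@dataclass
class ClickEvent:
    """One click as received across channels."""

    time_s: float                                  # reference (peak-channel) time
    channels: tuple[int, ...]
    peak_times: dict[int, float]                   # per-channel envelope peak, s
    levels_db: dict[int, float]                    # per-channel pp level
    snippets: dict[int, ClickWaveform]
    echo_ratio_db: float                           # trailing max re direct peak

    @property
    def peak_channel(self) -> int:
        return max(self.levels_db, key=self.levels_db.get)

    @property
    def peak_level_db(self) -> float:
        return self.levels_db[self.peak_channel]


@dataclass
class ScanSegment:
    clicks: list[ClickEvent]

    def __post_init__(self) -> None:
        self.clicks = sorted(self.clicks, key=lambda e: e.time_s)

    @property
    def ici_series_ms(self) -> np.ndarray:
        t = np.array([e.time_s for e in self.clicks])
        return np.diff(t) * 1e3

    @property
    def peak_channel(self) -> int:
        return self.strongest_click.peak_channel

    @property
    def strongest_click(self) -> ClickEvent:
        return max(self.clicks, key=lambda e: e.peak_level_db)

    @property
    def is_buzz(self) -> bool:
        ici = self.ici_series_ms
        return ici.size > 0 and float(np.median(ici)) < DEFAULT_BUZZ_ICI_MS


@dataclass
class LocalizationResult:
    position: np.ndarray            # (x, y, z) m, y = 0 by line-array convention
    range_to_reference: float       # m
    tdoas: dict[int, float]         # s, re reference channel
    residual_rms: float             # s
    tl_rms_error: float             # dB
    azimuth_resolved: bool = False
    degenerate: bool = False


@dataclass
class OnAxisDecision:
    criteria_passed: dict[str, bool]
    accepted: bool
    reject_reason: str = ""
    click_index: int | None = None

    @classmethod
    def from_criteria(cls, crit: dict[str, bool], click_index: int | None,
                      reason: str = "") -> "OnAxisDecision":
        accepted = all(crit.values())
        if not accepted and not reason:
            reason = "failed criteria: " + ", ".join(
                k for k, v in crit.items() if not v
            )
        return cls(crit, accepted, reason, click_index)


@dataclass
class DetectorSettings:
    threshold_db: float = 20.0          # above the per-channel noise floor
    min_separation_ms: float = 1.5      # between detections on one channel
    snippet_ms: float = 2.0
    scan_gap_ms: float = DEFAULT_SCAN_GAP_MS
    buzz_ici_ms: float = DEFAULT_BUZZ_ICI_MS
    echo_window_ms: float = DEFAULT_ECHO_WINDOW_MS
    echo_guard_ms: float = 0.5          # dead time after the direct peak


def _channel_detections(
    x: np.ndarray, fs: float, s: DetectorSettings
) -> tuple[np.ndarray, np.ndarray]:
    """Envelope peak indices and envelope for one channel."""
    env = np.abs(hilbert(x))
    # Rayleigh envelope of Gaussian noise: median = sigma*sqrt(2 ln 2)
    sigma = np.median(env) / math.sqrt(2.0 * math.log(2.0))
    floor = max(sigma, np.max(env) * 1e-4)
    height = floor * 10.0 ** (s.threshold_db / 20.0)
    dist = max(1, int(s.min_separation_ms / 1e3 * fs))
    peaks, _ = find_peaks(env, height=height, distance=dist)
    return peaks, env


def detect_and_segment(
    recording: ArrayRecording,
    settings: DetectorSettings | None = None,
) -> list[ScanSegment]:
    """Detect clicks on all active channels and group them into scans.

    Detections coincident across channels (within the maximum
    inter-hydrophone travel time) are merged into one click event; events
    separated by less than the scan gap form one scan.  Returns an empty
    list when nothing is detected.
    """
    s = settings or DetectorSettings()
    geom = recording.geometry
    fs = recording.sample_rate
    if s.threshold_db <= 0:
        raise InvalidParameterError("threshold_db must be positive")

    act = list(geom.active_channels)
    pos = geom.positions[act]
    max_sep = max(
        np.linalg.norm(pos[i] - pos[j])
        for i in range(len(act)) for j in range(i + 1, len(act))
    )
    c = recording.environment.c()
    merge_window = max_sep / c + 0.3e-3

    per_ch: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    all_times = []
    for ch in act:
        peaks, env = _channel_detections(recording.samples[ch], fs, s)
        per_ch[ch] = (peaks, env)
        for p in peaks:
            all_times.append((p / fs, ch, p))
    if not all_times:
        return []
    all_times.sort()

    # greedy clustering of detections into click events
    clusters: list[list[tuple[float, int, int]]] = []
    for det in all_times:
        if clusters and det[0] - clusters[-1][0][0] <= merge_window:
            clusters[-1].append(det)
        else:
            clusters.append([det])

    half = int(s.snippet_ms * 1e-3 * fs / 2)  # snippet half-width, samples
    events: list[ClickEvent] = []
    for cl in clusters:
        peak_times: dict[int, float] = {}
        levels: dict[int, float] = {}
        snippets: dict[int, ClickWaveform] = {}
        for t, ch, p in cl:
            _, env = per_ch[ch]
            if ch in peak_times:
                # keep the earliest arrival per channel: the direct path
                # precedes any reflection, which the trailing-window echo
                # check (criterion v) then inspects
                continue
            lo = max(0, p - half)
            hi = min(recording.samples.shape[1], p + half)
            snip = recording.samples[ch, lo:hi]
            peak_times[ch] = p / fs
            levels[ch] = 20.0 * np.log10(max(np.max(snip) - np.min(snip), 1e-12))
            snippets[ch] = ClickWaveform(snip, fs, channel_id=ch,
                                         time_offset=lo / fs)
        pk_ch = max(levels, key=levels.get)
        pk_idx = int(peak_times[pk_ch] * fs)
        _, env = per_ch[pk_ch]
        g0 = pk_idx + int(s.echo_guard_ms * 1e-3 * fs)
        g1 = pk_idx + int(s.echo_window_ms * 1e-3 * fs)
        if g0 < env.size:
            trail = np.max(env[g0:min(g1, env.size)]) if g1 > g0 else 0.0
            echo_ratio = 20.0 * np.log10(max(trail, 1e-12) / env[pk_idx])
        else:
            echo_ratio = -np.inf
        events.append(
            ClickEvent(
                time_s=peak_times[pk_ch],
                channels=tuple(sorted(peak_times)),
                peak_times=peak_times,
                levels_db=levels,
                snippets=snippets,
                echo_ratio_db=float(echo_ratio),
            )
        )

    # group events into scans
    scans: list[list[ClickEvent]] = []
    for ev in sorted(events, key=lambda e: e.time_s):
        if scans and (ev.time_s - scans[-1][-1].time_s) * 1e3 <= s.scan_gap_ms:
            scans[-1].append(ev)
        else:
            scans.append([ev])
    return [ScanSegment(cl) for cl in scans]


def _xcorr_lag(a: np.ndarray, b: np.ndarray, fs: float) -> tuple[float, float]:
    """Sub-sample lag of ``a`` relative to ``b`` via cross-correlation.

    The peak is located on the *envelope* of the cross-correlation (the
    magnitude of its analytic signal) rather than on the raw waveform
    correlation: off-axis piston filtering can invert a click's polarity
    (2·J1(x)/x changes sign beyond the first null), which would bias a
    raw-correlation peak by half a carrier cycle.  The envelope peak is
    the group delay, insensitive to polarity and carrier phase, and is
    refined by parabolic interpolation.  Returns (lag_seconds,
    normalized peak correlation magnitude).
    """
    n = min(a.size, b.size)
    a = a[:n] - np.mean(a[:n])
    b = b[:n] - np.mean(b[:n])
    xc = np.correlate(a, b, mode="full")
    xe = np.abs(hilbert(xc))
    lags = np.arange(-n + 1, n)
    k = int(np.argmax(xe))
    if 0 < k < xe.size - 1:
        y0, y1, y2 = xe[k - 1], xe[k], xe[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -1, 1))
    else:
        delta = 0.0
    norm = math.sqrt(np.sum(a**2) * np.sum(b**2))
    rho = float(xe[k] / norm) if norm > 0 else 0.0
    return (lags[k] + delta) / fs, rho


def estimate_tdoas(
    event: ClickEvent,
    reference_channel: int,
    min_correlation: float = 0.2,
) -> tuple[dict[int, float], dict[int, bool]]:
    """Per-channel time differences of arrival re the reference channel.

    Returns (tdoas, reliable) where ``reliable[ch]`` is False when the
    normalized correlation peak fell below ``min_correlation``.
    """
    if reference_channel not in event.snippets:
        raise InvalidParameterError("reference channel missing from event")
    if len(event.snippets) < 4:
        raise InvalidParameterError("need snippets on at least 4 channels")
    ref = event.snippets[reference_channel]
    tdoas: dict[int, float] = {reference_channel: 0.0}
    reliable: dict[int, bool] = {reference_channel: True}
    for ch, snip in event.snippets.items():
        if ch == reference_channel:
            continue
        lag, rho = _xcorr_lag(snip.samples, ref.samples, snip.sample_rate)
        tdoas[ch] = lag + (snip.time_offset - ref.time_offset)
        reliable[ch] = rho >= min_correlation
    return tdoas, reliable


def _solve_rho_z(
    tdoas: dict[int, float],
    z_pos: dict[int, float],
    ref: int,
    c: float,
    starts: list[tuple[float, float]],
) -> tuple[np.ndarray, float]:
    """Least-squares (rho, z) fit to TDOAs for a vertical line array."""
    chans = [ch for ch in tdoas if ch != ref]
    obs = np.array([tdoas[ch] for ch in chans])
    z_i = np.array([z_pos[ch] for ch in chans])
    z_r = z_pos[ref]

    def resid(p):
        rho, z = p
        r_i = np.hypot(rho, z - z_i)
        r_r = math.hypot(rho, z - z_r)
        return (r_i - r_r) / c - obs

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=([0.1, -50.0], [2000.0, 200.0]),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise LocalizationError("localization solver failed to converge")
    rms = math.sqrt(2.0 * best.cost / obs.size)
    return best.x, rms


def localize(
    tdoas: dict[int, float],
    geometry: ArrayGeometry,
    sound_speed: float,
    alpha_db_per_m: float = 0.04,
    reference_channel: int | None = None,
) -> LocalizationResult:
    """Source position from TDOAs on the vertical line array.

    The solution is reported as (horizontal range, depth); azimuth is
    unresolved by a line array and the position is placed in the x–z
    plane.  ``tl_rms_error`` is the rms spread of the transmission loss
    20·log10(r) + α·r implied by leave-one-hydrophone-out sub-solutions,
    about the full-array solution.
    """
    ref = geometry.reference_channel if reference_channel is None else reference_channel
    if ref not in tdoas:
        raise InvalidParameterError("reference channel missing from TDOA set")
    if len(tdoas) < 4:
        raise InvalidParameterError("need TDOAs on at least 4 channels")
    z_pos = {ch: geometry.positions[ch, 2] for ch in tdoas}
    if np.ptp([abs(t) for t in tdoas.values()]) < 1e-12 and len(tdoas) >= 4:
        # all zeros on a (symmetric) array: source on the symmetry plane,
        # range unresolved
        return LocalizationResult(
            position=np.array([np.nan, 0.0, np.nan]),
            range_to_reference=np.nan,
            tdoas=dict(tdoas),
            residual_rms=0.0,
            tl_rms_error=np.inf,
            degenerate=True,
        )
    starts = [(rho, z) for rho in (5.0, 10.0, 20.0, 40.0, 80.0)
              for z in (0.0, 2.5, 5.0, 7.5, 10.0)]
    (rho, z), rms = _solve_rho_z(tdoas, z_pos, ref, sound_speed, starts)
    pos = np.array([rho, 0.0, z])
    r_ref = float(np.linalg.norm(pos - geometry.positions[ref]))

    def tl(r: float) -> float:
        return 20.0 * math.log10(max(r, 1e-6)) + alpha_db_per_m * r

    tl_full = tl(r_ref)
    tl_sub = []
    chans = sorted(tdoas)
    for omit in chans:
        remaining = [ch for ch in chans if ch != omit]
        if len(remaining) < 4:
            continue
        sub_ref = ref if ref in remaining else remaining[0]
        sub = {ch: tdoas[ch] - tdoas[sub_ref] for ch in remaining}
        try:
            (rho_s, z_s), _ = _solve_rho_z(sub, z_pos, sub_ref, sound_speed,
                                           starts + [(rho, z)])
        except LocalizationError:
            continue
        p_s = np.array([rho_s, 0.0, z_s])
        tl_sub.append(tl(float(np.linalg.norm(p_s - geometry.positions[ref]))))
    if tl_sub:
        tl_err = math.sqrt(np.mean((np.array(tl_sub) - tl_full) ** 2))
    else:
        tl_err = np.inf
    return LocalizationResult(
        position=pos,
        range_to_reference=r_ref,
        tdoas=dict(tdoas),
        residual_rms=rms,
        tl_rms_error=tl_err,
    )


#: middle hydrophone channels eligible for the on-axis peak (criterion iv)
MIDDLE_CHANNELS_6 = (1, 2, 3, 4)
MIDDLE_CHANNELS_5 = (1, 3, 4)     # with broken hydrophone 3 (index 2) dropped


def select_on_axis(
    scan: ScanSegment,
    loc: LocalizationResult | None = None,
    mode: str = "six_channel",
    buzz_ici_ms: float = DEFAULT_BUZZ_ICI_MS,
) -> OnAxisDecision:
    """Apply the six on-axis criteria to a scan; at most one click accepted.

    ``mode='five_channel'`` mirrors the array half with a broken
    hydrophone 3: channel index 2 is not required and the middle-channel
    criterion uses the three central remaining hydrophones.
    """
    if mode not in ("six_channel", "five_channel"):
        raise InvalidParameterError("mode must be six_channel or five_channel")
    required = set(range(6)) - ({2} if mode == "five_channel" else set())
    middle = MIDDLE_CHANNELS_5 if mode == "five_channel" else MIDDLE_CHANNELS_6

    ici = scan.ici_series_ms
    if ici.size > 0 and float(np.median(ici)) < buzz_ici_ms:
        crit = {k: False for k in ("i", "ii", "iii", "iv", "v", "vi")}
        return OnAxisDecision(crit, False, "buzz (ICI below threshold)", None)

    best_idx = max(range(len(scan.clicks)),
                   key=lambda i: scan.clicks[i].peak_level_db)
    click = scan.clicks[best_idx]
    crit = {
        "i": required.issubset(set(click.channels)),
        "ii": len(scan.clicks) >= 2,
        "iii": True,  # by construction: the strongest click of the scan
        "iv": click.peak_channel in middle,
        "v": click.echo_ratio_db < 0.0,
        "vi": True,   # exactly one candidate is ever returned per scan
    }
    return OnAxisDecision.from_criteria(crit, best_idx)
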