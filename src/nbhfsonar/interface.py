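"""File I/O, configuration and the end-to-end analysis pipeline.

CSV is the interchange format for all tables, YAML/JSON for configs, and
16-bit PCM RIFF WAV (plus a JSON ground-truth/calibration sidecar) for
audio.  ``run_pipeline`` chains simulate → detect → select → localize →
source level → beam pattern and emits per-stage tables plus a
machine-readable run manifest; reruns with the same config and seed are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import __version__
from . import array_processing as ap
from . import beam_pattern as bp
from . import click_metrics as cm
from . import source_level as sl
from . import synthetic_scene as ss
from .core import ArrayGeometry, ArrayRecording, EnvironmentProfile, InvalidParameterError

__all__ = [
    "PipelineConfig",
    "read_multichannel_wav",
    "write_multichannel_wav",
    "save_scene",
    "load_scene_config",
    "run_pipeline",
    "DEFAULT_SENSITIVITY_DB",
]

#: hydrophone sensitivity assumed when no sidecar calibration is present
DEFAULT_SENSITIVITY_DB = -221.0  # dB re 1 V/µPa


@dataclass
class Gates:
    max_range_m: float = sl.MAX_RANGE_M
    tl_error_db: float = sl.MAX_TL_RMS_ERROR_DB
    beam_range_m: float = bp.BEAM_MAX_RANGE_M

    def __post_init__(self) -> None:
        if self.max_range_m <= 0 or self.beam_range_m <= 0 or self.tl_error_db < 0:
            raise InvalidParameterError("gates must be positive")


@dataclass
class PipelineConfig:
    scene: ss.SceneConfig
    detector: ap.DetectorSettings = field(default_factory=ap.DetectorSettings)
    gates: Gates = field(default_factory=Gates)
    mode: str = "six_channel"
    absorption_formulation: str = "fisher_simmons"
    out_dir: Path | None = None

    @property
    def seed(self) -> int:
        return self.scene.seed


_ALLOWED_KEYS = {
    "scene": {"top_depth", "environment", "sources", "noise_spectral_level",
              "sample_rate", "seed", "max_range_m", "quantize_16bit",
              "surface_echo"},
    "environment": {"temperature", "salinity", "depth", "sound_speed", "ph"},
    "source": {"position", "heading", "fc_khz", "duration_10db_us", "sl_pp_db",
               "aperture_cm", "ici_sequence_ms", "aim_sweep"},
    "detector": {"threshold_db", "min_separation_ms", "snippet_ms",
                 "scan_gap_ms", "buzz_ici_ms", "echo_window_ms", "echo_guard_ms"},
    "gates": {"max_range_m", "tl_error_db", "beam_range_m"},
    "top": {"scene", "detector", "gates", "mode", "absorption_formulation",
            "out_dir"},
}


def _check_keys(d: dict, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise InvalidParameterError(
            f"unknown config keys in {context}: {sorted(unknown)}"
        )


def load_scene_config(path_or_dict) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file or an equivalent dict.

    Unknown keys are rejected.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(path_or_dict)
    _check_keys(raw, _ALLOWED_KEYS["top"], "top level")
    sc = dict(raw["scene"])
    _check_keys(sc, _ALLOWED_KEYS["scene"], "scene")
    envd = dict(sc.pop("environment"))
    _check_keys(envd, _ALLOWED_KEYS["environment"], "environment")
    env = EnvironmentProfile(**envd)
    geom = ArrayGeometry.default_vertical(top_depth=sc.pop("top_depth", 2.0))
    sources = []
    for sd in sc.pop("sources"):
        sd = dict(sd)
        _check_keys(sd, _ALLOWED_KEYS["source"], "source")
        for key in ("position", "heading"):
            if key in sd:
                sd[key] = tuple(sd[key])
        if "ici_sequence_ms" in sd:
            sd["ici_sequence_ms"] = tuple(sd["ici_sequence_ms"])
        if sd.get("aim_sweep"):
            sd["aim_sweep"] = tuple(tuple(p) for p in sd["aim_sweep"])
        sources.append(ss.ClickSourceSpec(**sd))
    scene = ss.SceneConfig(geometry=geom, environment=env, sources=sources, **sc)
    det = ap.DetectorSettings(**raw.get("detector", {}))
    _check_keys(raw.get("detector", {}), _ALLOWED_KEYS["detector"], "detector")
    gd = raw.get("gates", {})
    _check_keys(gd, _ALLOWED_KEYS["gates"], "gates")
    gates = Gates(**gd)
    out_dir = raw.get("out_dir")
    return PipelineConfig(
        scene=scene,
        detector=det,
        gates=gates,
        mode=raw.get("mode", "six_channel"),
        absorption_formulation=raw.get("absorption_formulation", "fisher_simmons"),
        out_dir=Path(out_dir) if out_dir else None,
    )


def write_multichannel_wav(recording: ArrayRecording, path) -> Path:
    """Write a recording as 16-bit PCM WAV plus a JSON sidecar.

    The sidecar stores the µPa-per-count calibration (and the simulator's
    ground truth when present) so a read round-trip restores bit-identical
    pressures.
    """
    path = Path(path)
    cal = recording.ground_truth.get("calibration_upa_per_count")
    if cal is None:
        peak = np.max(np.abs(recording.samples))
        cal = peak / (0.5 * 32767.0) if peak > 0 else 1.0
    counts = np.round(recording.samples / cal)
    if np.max(np.abs(counts)) > 32767:
        raise InvalidParameterError("samples exceed 16-bit full scale")
    wavfile.write(path, int(recording.sample_rate),
                  counts.T.astype(np.int16))
    sidecar = dict(recording.ground_truth)
    sidecar["calibration_upa_per_count"] = cal
    sidecar["environment"] = asdict(recording.environment)
    sidecar["geometry_positions"] = recording.geometry.positions.tolist()
    sidecar["active_channels"] = list(recording.geometry.active_channels)
    sidecar["reference_channel"] = recording.geometry.reference_channel
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_multichannel_wav(
    path,
    geometry: ArrayGeometry | None = None,
    environment: EnvironmentProfile | None = None,
    sensitivity_db: float = DEFAULT_SENSITIVITY_DB,
    gain_db: float = 0.0,
    fullscale_volts: float = 1.0,
) -> ArrayRecording:
    """Read a multichannel WAV into a calibrated ArrayRecording.

    If a JSON sidecar sits next to the file its calibration, geometry and
    environment are used (missing arguments only).  Otherwise counts are
    converted via full-scale voltage, amplifier gain and hydrophone
    sensitivity: with the default −221 dB re 1V/µPa and 1 V full scale, a
    full-scale sample maps to 221 dB re 1 µPa.
    """
    path = Path(path)
    fs, data = wavfile.read(path)
    if data.ndim == 1:
        data = data[:, None]
    if not np.issubdtype(data.dtype, np.integer) and not np.issubdtype(
        data.dtype, np.floating
    ):
        raise InvalidParameterError(f"unsupported WAV encoding {data.dtype}")
    data = data.T.astype(float)

    sidecar = {}
    sc_path = path.with_suffix(".json")
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    if geometry is None:
        if "geometry_positions" in sidecar:
            geometry = ArrayGeometry(
                np.asarray(sidecar["geometry_positions"]),
                active_channels=tuple(sidecar.get(
                    "active_channels", range(len(sidecar["geometry_positions"])))),
                reference_channel=sidecar.get("reference_channel", 0),
            )
        else:
            geometry = ArrayGeometry.default_vertical()
    if data.shape[0] != geometry.n_channels:
        raise InvalidParameterError(
            f"WAV has {data.shape[0]} channels but geometry defines "
            f"{geometry.n_channels}"
        )
    if environment is None:
        if "environment" in sidecar:
            environment = EnvironmentProfile(**sidecar["environment"])
        else:
            environment = EnvironmentProfile(temperature=9.2, salinity=33.9)

    cal = sidecar.get("calibration_upa_per_count")
    if cal is None:
        if np.issubdtype(wavfile.read(path)[1].dtype, np.integer):
            volts = fullscale_volts / 32768.0
        else:
            volts = fullscale_volts
        cal = volts / 10.0 ** ((sensitivity_db + gain_db) / 20.0)
    samples = data * cal
    return ArrayRecording(samples, float(fs), geometry, environment,
                          ground_truth=sidecar)


def save_scene(scene: ss.SceneConfig, out_dir) -> Path:
    """Render a scene and write WAV + ground-truth sidecar into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = ss.render_array_recording(scene)
    return write_multichannel_wav(rec, out_dir / "scene.wav")


def _analyze_recording(
    recording: ArrayRecording, cfg: PipelineConfig
) -> dict:
    """detect → select → localize → source level → beam for one recording."""
    env = recording.environment
    c = env.c()
    scans = ap.detect_and_segment(recording, cfg.detector)
    log = {
        "n_scans": len(scans),
        "n_clicks_detected": int(sum(len(s.clicks) for s in scans)),
        "rejections": {},
        "n_accepted": 0,
    }
    click_rows, loc_rows, accepted = [], [], []
    for i_scan, scan in enumerate(scans):
        decision = ap.select_on_axis(scan, mode=cfg.mode,
                                     buzz_ici_ms=cfg.detector.buzz_ici_ms)
        if not decision.accepted:
            for k, ok in decision.criteria_passed.items():
                if not ok:
                    log["rejections"][k] = log["rejections"].get(k, 0) + 1
            continue
        click = scan.clicks[decision.click_index]
        try:
            tdoas, reliable = ap.estimate_tdoas(
                click, recording.geometry.reference_channel
            )
        except InvalidParameterError:
            log["rejections"]["tdoa"] = log["rejections"].get("tdoa", 0) + 1
            continue
        tdoas = {ch: t for ch, t in tdoas.items() if reliable[ch]}
        if len(tdoas) < 4:
            log["rejections"]["tdoa"] = log["rejections"].get("tdoa", 0) + 1
            continue
        # provisional absorption at the population-typical NBHF frequency;
        # refined below once the click's centroid frequency is measured
        alpha0 = sl.absorption_coefficient(130.0, env, cfg.absorption_formulation)
        try:
            loc = ap.localize(tdoas, recording.geometry, c, alpha0)
        except ap.LocalizationError:
            log["rejections"]["localization"] = (
                log["rejections"].get("localization", 0) + 1)
            continue
        if loc.degenerate:
            log["rejections"]["localization"] = (
                log["rejections"].get("localization", 0) + 1)
            continue
        params = cm.measure_click(click.snippets[click.peak_channel])
        alpha = sl.absorption_coefficient(
            float(np.clip(params.f_centroid, 10.0, 250.0)),
            env, cfg.absorption_formulation)
        gate_ok = (loc.range_to_reference <= cfg.gates.max_range_m
                   and loc.tl_rms_error < cfg.gates.tl_error_db)
        sl_est = None
        if gate_ok:
            sl_est = sl.apparent_source_level(params, loc, alpha,
                                              enforce_gate=False)
            log["n_accepted"] += 1
        else:
            log["rejections"]["range_gate"] = (
                log["rejections"].get("range_gate", 0) + 1)
        ici_prev = None
        times = [e.time_s for e in scan.clicks]
        idx = decision.click_index
        if idx > 0:
            ici_prev = (times[idx] - times[idx - 1]) * 1e3
        row = {"scan": i_scan, "time_s": click.time_s,
               "peak_channel": click.peak_channel,
               "range_m": loc.range_to_reference,
               "tl_rms_error_db": loc.tl_rms_error,
               "ici_ms": ici_prev, "gate_passed": gate_ok,
               **params.as_dict()}
        if sl_est is not None:
            row.update(sl_pp_db=sl_est.sl_pp, sl_rms_db=sl_est.sl_rms,
                       sl_efd_db=sl_est.sl_efd, tl_db=sl_est.tl)
            accepted.append({
                "click_id": i_scan,
                "position": loc.position,
                "onaxis_channel": click.peak_channel,
                "levels_db": dict(click.levels_db),
                "range_m": loc.range_to_reference,
                "f_centroid_khz": params.f_centroid,
            })
        click_rows.append(row)
        loc_rows.append({"scan": i_scan, "range_m": loc.range_to_reference,
                         "depth_m": loc.position[2],
                         "tl_rms_error_db": loc.tl_rms_error,
                         "residual_rms_s": loc.residual_rms})

    clicks_df = pd.DataFrame(click_rows)
    locs_df = pd.DataFrame(loc_rows)

    beam_samples, piston = [], None
    if accepted:
        fc_mean = float(np.mean([a["f_centroid_khz"] for a in accepted]))
        alpha_beam = sl.absorption_coefficient(
            float(np.clip(fc_mean, 10.0, 250.0)), env,
            cfg.absorption_formulation)
        beam_samples = bp.build_composite_beam(
            accepted, recording.geometry, alpha_beam,
            max_range_m=cfg.gates.beam_range_m)
        try:
            piston = bp.fit_piston_beam(beam_samples, fc_mean, c)
        except (InvalidParameterError, RuntimeError):
            piston = None
    beam_df = pd.DataFrame(
        [{"angle_deg": s.angle_deg, "relative_level_db": s.relative_level_db,
          "click_id": s.click_id, "channel_id": s.channel_id}
         for s in beam_samples]
    )
    return {"clicks": clicks_df, "localizations": locs_df, "beam": beam_df,
            "piston_fit": piston, "log": log}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate the configured scene and run the full analysis chain.

    Returns a result bundle with the per-stage tables, the piston fit,
    the structured stage log and a manifest; if ``cfg.out_dir`` is set,
    all tables plus the manifest are written there as CSV/JSON.
    """
    recording = ss.render_array_recording(cfg.scene)
    result = _analyze_recording(recording, cfg)
    result["recording"] = recording

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "gates": asdict(cfg.gates),
        "detector": asdict(cfg.detector),
        "absorption_formulation": cfg.absorption_formulation,
        "counts": result["log"],
    }
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hashes = {}
        for name in ("clicks", "localizations", "beam"):
            p = out / f"{name}.csv"
            result[name].to_csv(p, index=False)
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
        if result["piston_fit"] is not None:
            (out / "piston_fit.json").write_text(
                json.dumps(asdict(result["piston_fit"])))
        manifest["output_sha256"] = hashes
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result["manifest"] = manifest
    return result
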