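"""Detection, scan grouping, TDOA estimation, localization, on-axis
criteria."""

import numpy as np
import pytest

from nbhfsonar import array_processing as ap
from nbhfsonar import synthetic_scene as ss
from nbhfsonar.core import ClickWaveform, InvalidParameterError

from conftest import make_scan_source, make_scene

FS = 500_000.0


class TestDetection:
    def test_all_clicks_detected_on_all_channels(self, scan_recording_30m):
        scans = ap.detect_and_segment(scan_recording_30m)
        assert len(scans) == 1
        assert len(scans[0].clicks) == 7
        for click in scans[0].clicks:
            assert set(click.channels) == set(range(6))

    def test_detector_deterministic(self, scan_recording_30m):
        a = ap.detect_and_segment(scan_recording_30m)
        b = ap.detect_and_segment(scan_recording_30m)
        assert [c.time_s for c in a[0].clicks] == [c.time_s for c in b[0].clicks]

    def test_empty_recording_gives_empty_list(self, bc_env, geometry):
        scene = make_scene([make_scan_source(30.0)], bc_env, geometry, seed=3)
        rec = ss.render_array_recording(scene)
        silent = type(rec)(np.zeros_like(rec.samples) , rec.sample_rate,
                           rec.geometry, rec.environment)
        assert ap.detect_and_segment(silent) == []

    def test_scan_gap_splits_scans(self, bc_env, geometry):
        src = ss.ClickSourceSpec(
            position=(20.0, 0.0, 4.25), fc_khz=137.0, duration_10db_us=104.0,
            sl_pp_db=183.0, aperture_cm=10.0,
            ici_sequence_ms=(60.0, 60.0, 500.0, 60.0, 60.0),
            aim_sweep=((0.0, 0.0, 2.0), (0.0, 0.0, 6.5)),
        )
        rec = ss.render_array_recording(make_scene([src], bc_env, geometry, seed=4))
        scans = ap.detect_and_segment(rec)
        assert len(scans) == 2
        assert len(scans[0].clicks) == 3 and len(scans[1].clicks) == 3


class TestTdoa:
    def _event(self, snippets):
        return ap.ClickEvent(
            time_s=0.0, channels=tuple(snippets), peak_times={c: 0.0 for c in snippets},
            levels_db={c: 0.0 for c in snippets}, snippets=snippets,
            echo_ratio_db=-np.inf,
        )

    def test_identical_snippets_zero_tdoa(self):
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        pad = np.concatenate([np.zeros(100), w.samples, np.zeros(100)])
        snips = {ch: ClickWaveform(pad, FS, channel_id=ch) for ch in range(4)}
        tdoas, rel = ap.estimate_tdoas(self._event(snips), 0)
        assert all(abs(t) < 1e-7 for t in tdoas.values())
        assert all(rel.values())

    def test_known_integer_shift_recovered(self):
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        base = np.concatenate([np.zeros(120), w.samples, np.zeros(120)])
        shifted = np.roll(base, 17)
        snips = {
            0: ClickWaveform(base, FS),
            1: ClickWaveform(shifted, FS),
            2: ClickWaveform(base, FS),
            3: ClickWaveform(base, FS),
        }
        tdoas, _ = ap.estimate_tdoas(self._event(snips), 0)
        assert tdoas[1] == pytest.approx(17 / FS, abs=0.5e-6)

    def test_tdoas_match_scene_geometry(self, scan_recording_30m, geometry, bc_env):
        scans = ap.detect_and_segment(scan_recording_30m)
        click = scans[0].strongest_click
        tdoas, _ = ap.estimate_tdoas(click, 0)
        pos = np.array([30.0, 0.0, 4.25])
        r = np.linalg.norm(geometry.positions - pos, axis=1)
        expected = (r - r[0]) / bc_env.c()
        for ch in range(6):
            assert tdoas[ch] == pytest.approx(expected[ch], abs=2.0 / FS)


class TestLocalization:
    def exact_tdoas(self, pos, geometry, c):
        r = np.linalg.norm(geometry.positions - np.asarray(pos), axis=1)
        return {ch: (r[ch] - r[0]) / c for ch in range(6)}

    def test_noiseless_source_recovered(self, geometry, bc_env):
        c = bc_env.c()
        tdoas = self.exact_tdoas((30.0, 0.0, 4.0), geometry, c)
        loc = ap.localize(tdoas, geometry, c, 0.039)
        r_true = np.linalg.norm(np.array([30.0, 0.0, 4.0]) - geometry.positions[0])
        assert loc.range_to_reference == pytest.approx(r_true, abs=0.5)
        assert loc.position[2] == pytest.approx(4.0, abs=0.5)
        assert loc.tl_rms_error < 0.1

    @pytest.mark.parametrize("r", [10.0, 40.0, 65.0])
    def test_range_error_below_2_percent(self, geometry, bc_env, r):
        c = bc_env.c()
        tdoas = self.exact_tdoas((r, 0.0, 4.0), geometry, c)
        loc = ap.localize(tdoas, geometry, c, 0.039)
        r_true = np.linalg.norm(np.array([r, 0.0, 4.0]) - geometry.positions[0])
        assert abs(loc.range_to_reference - r_true) / r_true < 0.02

    def test_tl_error_monotone_with_tdoa_jitter(self, geometry, bc_env):
        c = bc_env.c()
        clean = self.exact_tdoas((40.0, 0.0, 4.0), geometry, c)
        rng = np.random.default_rng(0)
        noise = rng.normal(0.0, 1.0, 6)
        noise[0] = 0.0
        errs = []
        for jitter_us in (0.0, 2.0, 8.0):
            tdoas = {ch: t + noise[ch] * jitter_us * 1e-6
                     for ch, t in clean.items()}
            errs.append(ap.localize(tdoas, geometry, c, 0.039).tl_rms_error)
        assert errs[0] < errs[1] < errs[2]

    def test_all_zero_tdoas_degenerate(self, geometry, bc_env):
        loc = ap.localize({ch: 0.0 for ch in range(6)}, geometry, bc_env.c(), 0.04)
        assert loc.degenerate
        assert not np.isfinite(loc.range_to_reference)

    def test_too_few_channels_rejected(self, geometry, bc_env):
        with pytest.raises(InvalidParameterError):
            ap.localize({0: 0.0, 1: 1e-4, 2: 2e-4}, geometry, bc_env.c(), 0.04)


class TestOnAxisCriteria:
    def test_central_click_accepted(self, pipeline_result_30m, scan_recording_30m):
        """The sweep's central click (true on-axis channel 2) is accepted."""
        scans = ap.detect_and_segment(scan_recording_30m)
        decision = ap.select_on_axis(scans[0])
        assert decision.accepted
        click = scans[0].clicks[decision.click_index]
        assert click.peak_channel == scan_recording_30m.ground_truth["clicks"][3][
            "onaxis_channel"
        ]

    def test_peak_on_top_channel_fails_criterion_iv(self, bc_env, geometry):
        src = make_scan_source(25.0)
        src = ss.ClickSourceSpec(
            position=src.position, fc_khz=137.0, duration_10db_us=104.0,
            sl_pp_db=183.0, aperture_cm=10.0, ici_sequence_ms=(60.0, 60.0),
            aim_sweep=((0.0, 0.0, 1.0), (0.0, 0.0, 2.0)),  # sweeps onto the top
        )
        rec = ss.render_array_recording(make_scene([src], bc_env, geometry, seed=8))
        scans = ap.detect_and_segment(rec)
        decision = ap.select_on_axis(scans[0])
        assert not decision.accepted
        assert not decision.criteria_passed["iv"]

    def test_surface_echo_fails_criterion_v(self, bc_env, geometry):
        scene = make_scene([make_scan_source(20.0)], bc_env, geometry, seed=9,
                           surface_echo={"delay_ms": 3.0, "rel_db": 2.0})
        rec = ss.render_array_recording(scene)
        scans = ap.detect_and_segment(rec)
        decision = ap.select_on_axis(scans[0])
        assert not decision.criteria_passed["v"]

    def test_buzz_scan_excluded(self, bc_env, geometry):
        src = make_scan_source(15.0, ici_ms=5.0)  # ICI below buzz threshold
        rec = ss.render_array_recording(make_scene([src], bc_env, geometry, seed=10))
        scans = ap.detect_and_segment(rec)
        decision = ap.select_on_axis(scans[0])
        assert not decision.accepted
        assert "buzz" in decision.reject_reason

    def test_single_click_scan_fails_criterion_ii(self, bc_env, geometry):
        src = ss.ClickSourceSpec(position=(20.0, 0.0, 4.25),
                                 heading=(-1.0, 0.0, 0.02),
                                 fc_khz=137.0, duration_10db_us=104.0,
                                 sl_pp_db=183.0, aperture_cm=10.0)
        rec = ss.render_array_recording(make_scene([src], bc_env, geometry, seed=11))
        scans = ap.detect_and_segment(rec)
        decision = ap.select_on_axis(scans[0])
        assert not decision.criteria_passed["ii"]
        assert not decision.accepted

    def test_five_channel_mode_relaxes_criterion_i(self, bc_env):
        """With hydrophone 3 (channel 2) dead, five-channel mode accepts
        clicks missing that channel while six-channel mode rejects them."""
        from nbhfsonar.core import ArrayGeometry

        geom5 = ArrayGeometry.default_vertical(
            active_channels=(0, 1, 3, 4, 5)
        )
        src = make_scan_source(20.0)
        rec = ss.render_array_recording(make_scene([src], bc_env, geom5, seed=12))
        scans = ap.detect_and_segment(rec)
        dec6 = ap.select_on_axis(scans[0], mode="six_channel")
        dec5 = ap.select_on_axis(scans[0], mode="five_channel")
        assert not dec6.criteria_passed["i"]
        assert dec5.criteria_passed["i"]

    def test_at_most_one_accepted_per_scan(self, scan_recording_30m):
        scans = ap.detect_and_segment(scan_recording_30m)
        for scan in scans:
            decision = ap.select_on_axis(scan)
            accepted = 1 if decision.accepted else 0
            assert accepted <= 1
            assert decision.criteria_passed["vi"]
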