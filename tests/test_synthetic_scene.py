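"""Synthetic scene generator: waveform, beam, propagation, populations."""

import numpy as np
import pytest

from nbhfsonar import array_processing as ap
from nbhfsonar import click_metrics as cm
from nbhfsonar import source_level as sl
from nbhfsonar import synthetic_scene as ss
from nbhfsonar.core import ClickWaveform, EnvironmentProfile, InvalidParameterError

from conftest import make_scan_source, make_scene

FS = 500_000.0


class TestWaveform:
    @pytest.mark.parametrize(
        "fc,dur", [(130.0, 100.0), (137.0, 104.0), (141.0, 88.0), (136.0, 54.0)]
    )
    def test_roundtrip_centroid_and_duration(self, fc, dur):
        w = ss.generate_nbhf_waveform(fc, dur, FS)
        assert np.max(np.abs(w.samples)) == pytest.approx(1.0, abs=1e-6)
        p = cm.measure_click(w)
        assert p.f_centroid == pytest.approx(fc, abs=0.5)
        # within one sample of the requested -10 dB duration
        assert p.duration_10db == pytest.approx(dur, abs=2.0)

    def test_rms_bandwidth_matches_bruteforce_dft(self):
        """Measured rms bandwidth vs a direct DFT of the analytic pip."""
        fc, dur = 130.0, 100.0
        w = ss.generate_nbhf_waveform(fc, dur, FS)
        p = cm.measure_click(w)
        # oracle: direct Fourier sum of the analytically defined pip on a
        # fine frequency grid, then the energy-weighted spread about the
        # median-energy frequency
        t = w.times
        f = np.arange(50.0, 250.0, 0.05) * 1e3
        spec = np.abs(np.exp(-2j * np.pi * f[:, None] * t[None, :]) @ w.samples) ** 2
        cumsum = np.cumsum(spec)
        f_med = np.interp(cumsum[-1] / 2, cumsum, f) / 1e3
        bw = np.sqrt(np.sum(spec * (f / 1e3 - f_med) ** 2) / np.sum(spec))
        assert p.bw_rms == pytest.approx(bw, rel=0.02)
        # closed form for a Gaussian pip: sigma_f = 1/(2*sqrt(2)*pi*sigma_t)
        sigma_t = dur * 1e-6 / ss.GAUSS_10DB_WIDTH
        assert bw == pytest.approx(1e-3 / (2 * np.sqrt(2) * np.pi * sigma_t), rel=0.01)

    @pytest.mark.parametrize("fc,dur", [(130.0, 100.0), (137.0, 54.0)])
    def test_no_energy_below_100khz(self, fc, dur):
        """NBHF clicks carry essentially no energy below 100 kHz."""
        w = ss.generate_nbhf_waveform(fc, dur, FS)
        spec = np.abs(np.fft.rfft(w.samples)) ** 2
        f = np.fft.rfftfreq(w.samples.size, 1 / FS)
        low = np.sum(spec[f < 100e3])
        assert low / np.sum(spec) < 0.01
        # and nothing above -40 dB re the spectral peak below 100 kHz
        assert np.max(spec[f < 100e3]) < np.max(spec) * 1e-4

    def test_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            ss.generate_nbhf_waveform(260.0, 100.0, FS)


class TestPiston:
    def test_onaxis_identity(self):
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        out = ss.apply_piston_offaxis(w, 0.0, 10.0, 1480.0)
        assert np.array_equal(out.samples, w.samples)

    def test_first_null_attenuation(self):
        """At the first Bessel null the narrowband level drops >= 40 dB."""
        c = 1480.0
        theta = 10.0
        k = 2 * np.pi * 137e3 / c
        a = 3.8317059702075125 / (k * np.sin(np.radians(theta)))
        # long pip -> very narrow band, so the null is barely filled
        w = ss.generate_nbhf_waveform(137.0, 600.0, FS)
        out = ss.apply_piston_offaxis(w, theta, a * 200.0, c)
        drop = 20 * np.log10(np.max(np.abs(w.samples)) / np.max(np.abs(out.samples)))
        assert drop >= 40.0

    def test_mainlobe_monotone_decline(self):
        c = 1480.0
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        peaks = []
        for ang in (0.0, 2.0, 4.0, 6.0):
            out = ss.apply_piston_offaxis(w, ang, 10.0, c)
            peaks.append(np.max(np.abs(out.samples)))
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_negative_aperture_rejected(self):
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        with pytest.raises(InvalidParameterError):
            ss.apply_piston_offaxis(w, 5.0, -1.0, 1480.0)


class TestPropagation:
    def test_reference_range_identity(self, bc_env):
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        out = ss.propagate_click(w, 1.0, bc_env, absorption=False)
        assert np.max(np.abs(out.samples)) == pytest.approx(
            np.max(np.abs(w.samples)), rel=1e-9
        )
        assert out.time_offset - w.time_offset == pytest.approx(
            1.0 / bc_env.c(), rel=1e-9
        )

    def test_spherical_spreading_doubling(self, bc_env):
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        p10 = ss.propagate_click(w, 10.0, bc_env, absorption=False)
        p20 = ss.propagate_click(w, 20.0, bc_env, absorption=False)
        drop = 20 * np.log10(np.max(np.abs(p10.samples)) / np.max(np.abs(p20.samples)))
        assert drop == pytest.approx(20 * np.log10(2), abs=1e-6)

    def test_broadband_drop_matches_scalar_oracle(self, bc_env):
        """100 m propagation loses 40 dB spreading + 100·α(fc) absorption."""
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        out = ss.propagate_click(w, 100.0, bc_env)
        alpha = sl.absorption_coefficient(137.0, bc_env)
        drop = 20 * np.log10(np.max(np.abs(w.samples)) / np.max(np.abs(out.samples)))
        assert drop == pytest.approx(40.0 + 100.0 * alpha, abs=0.5)

    def test_energy_conservation_roundtrip(self, bc_env):
        """Back-correcting by TL at the centroid restores the level
        within 0.1 dB (noiseless)."""
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        p0 = cm.measure_click(w)
        for r in (10.0, 40.0, 65.0):
            out = ss.propagate_click(w, r, bc_env)
            p = cm.measure_click(out)
            alpha = sl.absorption_coefficient(p.f_centroid, bc_env)
            tl = sl.transmission_loss(r, alpha)
            assert p.rl_pp + tl == pytest.approx(p0.rl_pp, abs=0.1)

    def test_nonpositive_range_rejected(self, bc_env):
        w = ss.generate_nbhf_waveform(137.0, 104.0, FS)
        with pytest.raises(InvalidParameterError):
            ss.propagate_click(w, 0.0, bc_env)


class TestPopulations:
    def test_sample_means_match_study_populations(self):
        specs = ss.sample_population_parameters("bc_dalls", 10_000, seed=1)
        fc = np.array([s.fc_khz for s in specs])
        assert fc.mean() == pytest.approx(137.0, abs=0.1)
        # bc_harbour's range truncation (lower bound 1.5 SD below the
        # mean) shifts the realized mean up by ~0.3 kHz
        specs = ss.sample_population_parameters("bc_harbour", 10_000, seed=1)
        fc = np.array([s.fc_khz for s in specs])
        assert 141.0 < fc.mean() < 141.5
        specs = ss.sample_population_parameters(
            "bc_harbour", 10_000, seed=1, truncate=False
        )
        fc = np.array([s.fc_khz for s in specs])
        assert fc.mean() == pytest.approx(141.0, abs=0.1)

    def test_truncation_respects_ranges(self):
        specs = ss.sample_population_parameters("dk_harbour", 5_000, seed=2)
        dur = np.array([s.duration_10db_us for s in specs])
        assert dur.min() >= 35.0 and dur.max() <= 98.0

    def test_seed_determinism(self):
        a = ss.sample_population_parameters("bc_dalls", 1, seed=42)[0]
        b = ss.sample_population_parameters("bc_dalls", 1, seed=42)[0]
        assert a.fc_khz == b.fc_khz and a.sl_pp_db == b.sl_pp_db

    def test_unknown_population_rejected(self):
        with pytest.raises(InvalidParameterError):
            ss.sample_population_parameters("orca", 10, seed=0)


class TestRender:
    def test_tdoa_symmetry_on_bisector_plane(self, bc_env, geometry):
        """A source equidistant from two hydrophones gives zero TDOA."""
        # perpendicular bisector plane of hydrophones 0 (z=2.0) and 1 (z=3.5)
        src = ss.ClickSourceSpec(
            position=(20.0, 0.0, 2.75), heading=(-1.0, 0.0, 0.0),
            fc_khz=137.0, duration_10db_us=104.0, sl_pp_db=183.0,
            aperture_cm=10.0, ici_sequence_ms=(60.0,),
        )
        scene = make_scene([src], bc_env, geometry, seed=5)
        rec = ss.render_array_recording(scene)
        scans = ap.detect_and_segment(rec)
        tdoas, _ = ap.estimate_tdoas(scans[0].strongest_click, 0)
        assert abs(tdoas[1]) <= 2.0 / FS

    def test_received_level_matches_sonar_equation(self, bc_env, geometry):
        """RL on the on-axis channel = SL - TL(r) for a 20 m source."""
        src = make_scan_source(20.0, sl_pp_db=190.0)
        scene = make_scene([src], bc_env, geometry, seed=6)
        rec = ss.render_array_recording(scene)
        truth = rec.ground_truth["clicks"][3]  # the central, on-axis click
        ch = truth["onaxis_channel"]
        r = truth["ranges_m"][ch]
        scans = ap.detect_and_segment(rec)
        click = scans[0].strongest_click
        alpha = sl.absorption_coefficient(137.0, bc_env)
        expected = 190.0 - sl.transmission_loss(r, alpha)
        assert click.levels_db[ch] == pytest.approx(expected, abs=1.0)

    def test_render_deterministic_under_seed(self, bc_env, geometry):
        scene = make_scene([make_scan_source(15.0)], bc_env, geometry,
                           noise_spectral_level=55.0, seed=9)
        a = ss.render_array_recording(scene)
        b = ss.render_array_recording(scene)
        assert np.array_equal(a.samples, b.samples)

    def test_source_beyond_max_range_rejected(self, bc_env, geometry):
        src = make_scan_source(150.0)
        scene = make_scene([src], bc_env, geometry, seed=1)
        with pytest.raises(InvalidParameterError):
            ss.render_array_recording(scene)

    def test_source_on_array_axis_rejected(self, bc_env, geometry):
        src = ss.ClickSourceSpec(position=(0.0, 0.0, 30.0))
        scene = make_scene([src], bc_env, geometry, seed=1)
        with pytest.raises(InvalidParameterError):
            ss.render_array_recording(scene)
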