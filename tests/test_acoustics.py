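import numpy as np
import pytest
from scipy.special import j1

from echonav import (
    EmissionModel,
    Scatterer,
    ear_directivity,
    emitted_pulse,
    emitter_directivity,
    synthesize_echoes,
)
from echonav.acoustics import SPEED_OF_SOUND, recording_length

from conftest import lone_scatterer_env

FS = 300_000.0


class TestEmittedPulse:
    def test_duration_450_samples_at_300k(self, emission):
        assert len(emitted_pulse(emission, FS)) == 450  # 1.5 ms

    def test_zero_source_level(self):
        p = emitted_pulse(EmissionModel(source_level=0.0), FS)
        assert np.all(p == 0)

    def test_spectral_peak_at_carrier(self, emission):
        # DFT oracle: the burst's spectrum must peak at 40 kHz +/- one bin
        p = emitted_pulse(emission, FS)
        n = 1 << 14
        spec = np.abs(np.fft.rfft(p, n))
        freqs = np.fft.rfftfreq(n, 1 / FS)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - 40_000.0) <= FS / n + 1e-9

    def test_undersampling_rejected(self, emission):
        with pytest.raises(ValueError):
            emitted_pulse(emission, 100_000.0)


class TestEmitterDirectivity:
    def test_on_axis_unity(self, emission):
        assert emitter_directivity(0.0, emission) == pytest.approx(1.0)

    def test_even_in_azimuth(self, emission):
        az = np.linspace(0, 90, 19)
        np.testing.assert_allclose(
            emitter_directivity(az, emission), emitter_directivity(-az, emission)
        )

    def test_matches_piston_formula_at_30deg(self, emission):
        # independent evaluation of 2 J1(ka sin az)/(ka sin az)
        a, c = 0.005, SPEED_OF_SOUND
        k = 2 * np.pi * 40_000.0 / c
        x = k * a * np.sin(np.radians(30.0))
        assert emitter_directivity(30.0, emission) == pytest.approx(2 * j1(x) / x)

    def test_monotone_over_frontal_quadrant(self, emission):
        g = emitter_directivity(np.linspace(0, 90, 91), emission)
        assert np.all(np.diff(g) <= 1e-12)


class TestEarDirectivity:
    def test_midline_symmetry(self, ears):
        assert ear_directivity(0.0, "left", ears) == pytest.approx(
            ear_directivity(0.0, "right", ears)
        )

    def test_source_side_is_louder(self, ears):
        # positive azimuth = right of gaze -> right ear gain larger
        for az in (5, 20, 30, 45, 60):
            assert ear_directivity(az, "right", ears) > ear_directivity(az, "left", ears)

    def test_ild_antisymmetric(self, ears):
        az = np.linspace(-80, 80, 33)
        ild = ear_directivity(az, "right", ears) - ear_directivity(az, "left", ears)
        np.testing.assert_allclose(ild, -ild[::-1], atol=1e-12)

    def test_gain_peaks_at_offset(self, ears):
        az = np.linspace(-90, 90, 721)
        g = ear_directivity(az, "right", ears)
        assert az[np.argmax(g)] == pytest.approx(25.0, abs=0.5)

    def test_unknown_side_rejected(self, ears):
        with pytest.raises(ValueError):
            ear_directivity(0.0, "up", ears)


class TestSynthesizeEchoes:
    def test_empty_noiseless_scene_is_silent(self, emission, ears):
        from echonav import Environment

        env = Environment(kind="arena", walls=[], obstacles=[], scatterers=[], bounds=(-5, -5, 5, 5))
        rec = synthesize_echoes((0, 0), 0.0, env, emission, ears, noise_rms=0.0,
                                include_emission=False)
        assert np.all(rec.left == 0) and np.all(rec.right == 0)

    def test_single_scatterer_delay_and_balance(self, emission, ears):
        # echo onset at 2 r / c; dead ahead -> both ears identical
        env = lone_scatterer_env(1.0, 0.0)
        rec = synthesize_echoes((0, 0), 0.0, env, emission, ears, noise_rms=0.0,
                                include_emission=False)
        onset = np.flatnonzero(np.abs(rec.left) > 0)[0]
        # first nonzero sample within 2 samples of the 2r/c delay (~5.83 ms)
        assert abs(onset - 2 * 1.0 / SPEED_OF_SOUND * FS) <= 2
        np.testing.assert_allclose(rec.left, rec.right)

    def test_scatterer_right_of_gaze_louder_on_right(self, emission, ears):
        az = np.radians(20.0)
        # +20 deg azimuth = clockwise from gaze (gaze along +x)
        env = lone_scatterer_env(np.cos(az), -np.sin(az))
        rec = synthesize_echoes((0, 0), 0.0, env, emission, ears, noise_rms=0.0,
                                include_emission=False)
        assert np.sum(rec.right**2) > np.sum(rec.left**2)

    def test_rear_scatterers_excluded(self, emission, ears):
        env = lone_scatterer_env(-1.0, 0.0)  # behind the gaze
        rec = synthesize_echoes((0, 0), 0.0, env, emission, ears, noise_rms=0.0,
                                include_emission=False)
        assert np.all(rec.left == 0)

    def test_superposition(self, emission, ears):
        from echonav import Environment

        s1, s2 = Scatterer((1.0, 0.3), 0.02), Scatterer((1.7, -0.5), 0.05)
        def rec_for(scats):
            env = Environment(kind="arena", walls=[], obstacles=[], scatterers=scats,
                              bounds=(-10, -10, 10, 10))
            return synthesize_echoes((0, 0), 0.0, env, emission, ears, noise_rms=0.0,
                                     include_emission=False)
        both = rec_for([s1, s2])
        a, b = rec_for([s1]), rec_for([s2])
        np.testing.assert_allclose(both.left, a.left + b.left, atol=1e-15)
        np.testing.assert_allclose(both.right, a.right + b.right, atol=1e-15)

    def test_inverse_square_range_law(self, emission, ears):
        # doubling the range quarters the echo peak (absorption disabled)
        peaks = []
        for r in (1.0, 2.0):
            env = lone_scatterer_env(r, 0.0)
            rec = synthesize_echoes((0, 0), 0.0, env, emission, ears, noise_rms=0.0,
                                    absorption_db_per_m=0.0, include_emission=False)
            peaks.append(np.max(np.abs(rec.left)))
        assert peaks[0] / peaks[1] == pytest.approx(4.0, rel=1e-3)

    def test_mirror_symmetry_swaps_channels(self, emission, ears, arena):
        # reflecting the scene about the gaze axis swaps left and right
        from echonav import Environment

        mirrored = Environment(
            kind="arena",
            walls=arena.walls,
            obstacles=arena.obstacles,
            scatterers=[
                Scatterer((s.position[0], -s.position[1]), s.strength,
                          (s.normal[0], -s.normal[1]) if s.normal else None,
                          s.directivity_exponent)
                for s in arena.scatterers
            ],
            bounds=(arena.bounds[0], -arena.bounds[3], arena.bounds[2], -arena.bounds[1]),
        )
        kw = dict(noise_rms=0.0, include_emission=False)
        rec = synthesize_echoes((1.0, 0.5), 0.0, arena, emission, ears, **kw)
        mir = synthesize_echoes((1.0, -0.5), 0.0, mirrored, emission, ears, **kw)
        np.testing.assert_allclose(rec.left, mir.right, atol=1e-12)
        np.testing.assert_allclose(rec.right, mir.left, atol=1e-12)

    def test_noise_reproducible_under_seed(self, emission, ears, arena):
        kw = dict(noise_rms=1e-4, seed=7)
        a = synthesize_echoes((1.0, 0.5), 10.0, arena, emission, ears, **kw)
        b = synthesize_echoes((1.0, 0.5), 10.0, arena, emission, ears, **kw)
        np.testing.assert_array_equal(a.left, b.left)
        np.testing.assert_array_equal(a.right, b.right)

    def test_recording_covers_range_cap(self, emission):
        n = recording_length(emission, FS, range_cap=6.0)
        assert n >= 2 * 6.0 / SPEED_OF_SOUND * FS + 450  # 35 ms window + pulse

    def test_quasi_specular_wall_fades_off_normal(self, emission, ears):
        from echonav import Environment

        panel = Scatterer((1.0, 0.0), 0.05, normal=(-1.0, 0.0), directivity_exponent=8.0)
        env = Environment(kind="arena", walls=[], obstacles=[], scatterers=[panel],
                          bounds=(-10, -10, 10, 10))
        kw = dict(noise_rms=0.0, include_emission=False)
        head_on = synthesize_echoes((0.0, 0.0), 0.0, env, emission, ears, **kw)
        oblique = synthesize_echoes((0.3, 0.7), -40.0, env, emission, ears, **kw)
        assert np.max(np.abs(oblique.left)) < 0.1 * np.max(np.abs(head_on.left))
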