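"""Synthetic-data generator: layout geometry, background spectrum,
injected oscillations and plane-wave phase structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

import insulawaves as iw
from insulawaves.synth import GradientSpec, StudyConfig, WaveSpec


def probe_of(name: str) -> str:
    return name.split("-")[0]


class TestElectrodeLayout:
    def test_row_count_and_spacing_range(self):
        lay = iw.make_electrode_layout(1, 10, (3.5, 5.53), seed=1)
        assert len(lay) == 10
        for _, probe in lay.groupby(lay["name"].map(probe_of)):
            coords = probe[["x", "y", "z"]].to_numpy()
            d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            assert np.all((d >= 3.5) & (d <= 5.53))

    def test_exact_spacing_when_range_degenerate(self):
        lay = iw.make_electrode_layout(2, 4, (4.0, 4.0), seed=7)
        assert len(lay) == 8
        for _, probe in lay.groupby(["subject", lay["name"].map(probe_of)]):
            coords = probe[["x", "y", "z"]].to_numpy()
            d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            np.testing.assert_allclose(d, 4.0)

    def test_deterministic(self):
        a = iw.make_electrode_layout(2, 4, (4.0, 4.0), seed=7)
        b = iw.make_electrode_layout(2, 4, (4.0, 4.0), seed=7)
        assert a.to_csv() == b.to_csv()

    def test_both_hemispheres_when_count_permits(self):
        lay = iw.make_electrode_layout(1, 16, seed=3)
        assert set(lay["hemisphere"]) == {"left", "right"}

    @pytest.mark.parametrize("args", [
        (0, 10, (3.5, 5.53)), (1, 3, (3.5, 5.53)), (1, 10, (0.0, 5.0)),
        (1, 10, (5.0, 25.0)),
    ])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            iw.make_electrode_layout(*args, seed=0)

    def test_names_unique_within_subject(self):
        lay = iw.make_electrode_layout(3, 20, seed=5)
        assert not lay.groupby("subject")["name"].apply(
            lambda s: s.duplicated().any()).any()


class TestBackgroundNoise:
    def test_periodogram_slope_matches_exponent(self):
        fs, dur = 250.0, 100.0
        for exponent in (1.0, 2.0):
            x = iw.one_over_f_noise(int(fs * dur), fs, exponent, 10.0,
                                    np.random.default_rng(3))
            f, p = signal.welch(x, fs=fs, nperseg=4096)
            sel = (f >= 2) & (f <= 80)
            slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
            assert abs(slope + exponent) < 0.2

    def test_rms_scaling(self):
        x = iw.one_over_f_noise(10000, 250.0, 2.0, 7.0,
                                np.random.default_rng(0))
        assert x.std() == pytest.approx(7.0)


def _wave_only_config(**kw):
    base = dict(n_subjects=1, electrodes_per_subject=4,
                sampling_rate=500.0, duration=4.0,
                one_over_f_exponent=2.0, background_rms_uv=0.0,
                gradients=[], line_noise_uv=0.0, artifact_rate_per_min=0.0,
                seed=5)
    base.update(kw)
    return StudyConfig(**base)


class TestSimulateRecording:
    def test_plane_wave_phase_differences(self):
        """Electrodes 2 mm apart along the propagation direction differ by
        xi * 2 mm = 20 degrees in instantaneous phase."""
        layout = pd.DataFrame({
            "name": [f"e{i}" for i in range(4)],
            "x": [0.0, 2.0, 4.0, 6.0], "y": 0.0, "z": 0.0,
            "hemisphere": "left", "subject": "sub01"})
        spec = WaveSpec(electrodes=list(layout["name"]), subject="sub01",
                        f=20.0, alpha=0.0, xi=10.0, amplitude_uv=5.0)
        cfg = _wave_only_config(waves=[spec])
        rec, injected = iw.simulate_recording(layout, cfg)
        assert len(injected) == 1
        phases = np.angle(signal.hilbert(rec.data, axis=1))
        interior = slice(500, 1500)
        dphi = np.rad2deg(phases[1, interior] - phases[0, interior]) % 360.0
        # |phase difference| of 20 deg: the trailing electrode lags
        circ = np.minimum(dphi, 360.0 - dphi)
        np.testing.assert_allclose(circ, 20.0, atol=1e-6)

    def test_unknown_electrode_rejected(self):
        layout = pd.DataFrame({
            "name": ["a", "b", "c", "d"], "x": [0, 4, 8, 12.0],
            "y": 0.0, "z": 0.0, "hemisphere": "left", "subject": "sub01"})
        spec = WaveSpec(electrodes=["a", "nope", "c", "d"], subject="sub01",
                        f=10.0, alpha=0.0, xi=5.0, amplitude_uv=1.0)
        with pytest.raises(ValueError, match="unknown electrode"):
            iw.simulate_recording(layout, _wave_only_config(waves=[spec]))

    def test_gradient_center_frequencies_follow_slope(self):
        """With a -0.05 Hz/mm AP slope and no noise, each electrode's
        dominant frequency decreases with y at exactly that slope (up to
        the FFT resolution of the estimate)."""
        cfg = StudyConfig(
            n_subjects=1, electrodes_per_subject=8,
            sampling_rate=250.0, duration=40.0, background_rms_uv=0.0,
            gradients=[GradientSpec(band="theta", f0=7.5, amp_uv=3.0,
                                    freq_slope=-0.05)],
            line_noise_uv=0.0, artifact_rate_per_min=0.0, seed=9)
        study = iw.make_study(cfg)
        rec = study.recordings["sub01"]
        freqs = np.fft.rfftfreq(rec.n_samples, 1.0 / rec.fs)
        peak_f = freqs[np.argmax(np.abs(np.fft.rfft(rec.data, axis=1)), axis=1)]
        y = rec.electrodes["y"].to_numpy()
        slope = np.polyfit(y, peak_f, 1)[0]
        assert slope == pytest.approx(-0.05, abs=2.0 / cfg.duration)


class TestMakeStudy:
    def test_deterministic_bundle(self):
        cfg = iw.default_config(n_subjects=2, electrodes_per_subject=8,
                                sampling_rate=250.0, duration=5.0, seed=4)
        s1 = iw.make_study(cfg, auto_waves=True)
        s2 = iw.make_study(cfg, auto_waves=True)
        assert s1.electrodes.to_csv() == s2.electrodes.to_csv()
        assert s1.wave_truth.to_csv() == s2.wave_truth.to_csv()
        for sub in s1.recordings:
            np.testing.assert_array_equal(s1.recordings[sub].data,
                                          s2.recordings[sub].data)

    def test_no_waves_gives_empty_truth(self):
        cfg = iw.default_config(n_subjects=1, electrodes_per_subject=8,
                                sampling_rate=250.0, duration=2.0, seed=1)
        study = iw.make_study(cfg, auto_waves=False)
        assert study.wave_truth.empty

    def test_roundtrip_through_disk(self, tmp_path):
        cfg = iw.default_config(n_subjects=1, electrodes_per_subject=8,
                                sampling_rate=250.0, duration=2.0, seed=8)
        study = iw.make_study(cfg, auto_waves=True)
        iw.write_study(study, tmp_path)
        elec = iw.read_electrode_table(tmp_path / "electrodes.tsv")
        assert len(elec) == 8
        rec = iw.read_recording(tmp_path / "sub01_signals", electrodes=elec)
        assert rec.n_channels == 8
        np.testing.assert_allclose(rec.data, study.recordings["sub01"].data,
                                   atol=1e-3)  # float32 storage
        cfg2 = StudyConfig.from_json(tmp_path / "config.json")
        assert cfg2.seed == cfg.seed and cfg2.waves


class TestPlaneProjection:
    def test_coplanar_distances_preserved(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(-10, 10, (6, 2))
        # embed the plane arbitrarily in 3-D
        basis = np.linalg.qr(rng.standard_normal((3, 2)))[0].T
        coords3d = xy @ basis + np.array([5.0, -3.0, 2.0])
        proj, _ = iw.plane_coordinates(coords3d)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(proj), pdist(coords3d), atol=1e-9)
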