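"""Circular-linear plane-wave fitting, subclusters, phases and the
spatial-shuffle surrogate test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

import insulawaves as iw
from insulawaves.clusters import OscillationCluster
from insulawaves.io import Recording


def plane_phases(xy, alpha_deg, xi, offset=0.0):
    a = xi * np.cos(np.deg2rad(alpha_deg))
    b = xi * np.sin(np.deg2rad(alpha_deg))
    return (a * xy[:, 0] + b * xy[:, 1] + offset) % 360.0


class TestCircularLinearFit:
    @pytest.mark.parametrize("alpha,xi", [(90.0, 10.0), (0.0, 2.5),
                                          (215.0, 7.0)])
    def test_noiseless_wave_recovered_exactly(self, scatter_xy, alpha, xi):
        fit = iw.circular_linear_fit(plane_phases(scatter_xy, alpha, xi, 33.0),
                                     scatter_xy)
        assert fit.alpha == pytest.approx(alpha)
        assert fit.xi == pytest.approx(xi)
        assert fit.rbar == pytest.approx(1.0, abs=1e-9)
        assert fit.wave_strength == pytest.approx(1.0, abs=1e-9)
        assert fit.theta == pytest.approx(33.0, abs=1e-6)

    def test_constant_phases_degenerate(self, scatter_xy):
        fit = iw.circular_linear_fit(np.full(8, 120.0), scatter_xy)
        assert fit.xi == 0.0
        assert np.isnan(fit.alpha)
        assert fit.rbar == pytest.approx(1.0)
        assert np.isnan(fit.rho_cc)
        assert fit.wave_strength == 0.0

    def test_too_few_electrodes_rejected(self, scatter_xy):
        with pytest.raises(ValueError):
            iw.circular_linear_fit(np.array([0.0, 10.0, 20.0]),
                                   scatter_xy[:3])

    def test_rotation_equivariance(self, scatter_xy):
        """Rotating the electrode map by phi rotates the fitted angle by
        phi (mod 360), within one grid step."""
        phases = plane_phases(scatter_xy, 45.0, 8.0)
        phi = 40.0
        r = np.deg2rad(phi)
        rot = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        fit = iw.circular_linear_fit(phases, scatter_xy @ rot.T)
        delta = (fit.alpha - (45.0 + phi)) % 360.0
        assert min(delta, 360.0 - delta) <= 5.0

    def test_xi_capped_at_spatial_nyquist(self, scatter_xy):
        ny = iw.spatial_nyquist(scatter_xy)
        phases = plane_phases(scatter_xy, 10.0, 5.0)
        fit = iw.circular_linear_fit(phases, scatter_xy)
        assert fit.xi <= ny + 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rbar_and_strength_bounds_on_random_phases(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(-8, 8, (6, 2))
        phases = rng.uniform(0, 360, 6)
        fit = iw.circular_linear_fit(phases, xy)
        assert 0.0 <= fit.rbar <= 1.0 + 1e-12
        assert fit.wave_strength <= 1.0 + 1e-12
        assert fit.xi >= 0.0


class TestFitQuality:
    def test_perfect_prediction(self):
        th = np.array([10.0, 50.0, 90.0, 130.0, 170.0, 210.0])
        rho, r2 = iw.fit_quality(th, th)
        assert rho == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_prediction_flagged(self):
        th = np.array([10.0, 50.0, 90.0, 130.0, 170.0])
        rho, r2 = iw.fit_quality(th, np.full(5, 30.0))
        assert np.isnan(rho) and r2 == 0.0

    def test_adjustment_formula_arithmetic(self):
        assert iw.adjusted_wave_strength(0.0, n=10) == pytest.approx(-0.5)
        assert iw.adjusted_wave_strength(0.8, n=20) == pytest.approx(0.5725)
        for n in (6, 11, 50):
            assert iw.adjusted_wave_strength(1.0, n=n) == pytest.approx(1.0)

    def test_adjustment_shrinks_moderate_correlations(self):
        for rho in (0.3, 0.6, 0.9):
            assert iw.adjusted_wave_strength(rho, n=12) < rho ** 2

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            iw.adjusted_wave_strength(0.5, n=4)


class TestWaveSpeed:
    def test_printed_examples(self):
        assert iw.wave_speed(10.0, 20.0) == pytest.approx(0.72)
        assert iw.wave_speed(32.5, 8.0) == pytest.approx(0.0886, abs=1e-4)

    def test_doubling_xi_halves_speed(self):
        assert iw.wave_speed(20.0, 20.0) == pytest.approx(
            iw.wave_speed(10.0, 20.0) / 2.0)

    def test_degenerate_and_invalid(self):
        assert np.isnan(iw.wave_speed(0.0, 8.0))
        with pytest.raises(ValueError):
            iw.wave_speed(-1.0, 8.0)


class TestSpatialNyquist:
    def test_paper_spacing_gives_32_5(self):
        xy = np.array([[0.0, 0.0], [5.53, 0.0]])
        assert round(iw.spatial_nyquist(xy), 1) == 32.5


class TestPhaseTimeseries:
    def _cluster_rec(self, f_p=8.0, fs=500.0, dur=10.0, kind="cos"):
        t = np.arange(int(fs * dur)) / fs
        base = np.cos(2 * np.pi * f_p * t) if kind == "cos" else \
            np.random.default_rng(0).standard_normal(t.size)
        data = np.vstack([base] * 4)
        names = ["a", "b", "c", "d"]
        rec = Recording(data=data, fs=fs, channel_ids=names)
        cluster = OscillationCluster(cluster_id="c0", subject_id="s",
                                     hemisphere="left", band="theta",
                                     members=names, f_p=f_p)
        return rec, cluster, t

    def test_unwrapped_phase_slope_matches_frequency(self):
        rec, cluster, t = self._cluster_rec()
        field = iw.phase_timeseries(rec, cluster)
        interior = slice(1000, 4000)
        ph = np.unwrap(np.deg2rad(field.phases[0, interior]))
        slope = np.polyfit(t[interior], np.rad2deg(ph), 1)[0]
        assert slope == pytest.approx(360.0 * 8.0, rel=1e-3)

    def test_cosine_phase_zero_at_maxima(self):
        rec, cluster, _ = self._cluster_rec()
        field = iw.phase_timeseries(rec, cluster)
        peaks = signal.argrelmax(rec.data[0])[0]
        peaks = peaks[(peaks > 1000) & (peaks < 4000)]
        ph = field.phases[0, peaks]
        wrapped = np.minimum(ph, 360.0 - ph)
        assert np.max(np.abs(wrapped)) < 5.0

    def test_out_of_band_attenuation(self):
        rec, cluster, _ = self._cluster_rec(kind="noise")
        field = iw.phase_timeseries(rec, cluster)
        # reconstruct the filtered signal from the analytic representation
        filtered = field.amplitude[0] * np.cos(np.deg2rad(field.phases[0]))
        f, p_in = signal.periodogram(rec.data[0], fs=rec.fs)
        _, p_out = signal.periodogram(filtered, fs=rec.fs)
        i2f = np.argmin(np.abs(f - 16.0))
        sl = slice(max(i2f - 2, 0), i2f + 3)
        atten = 10 * np.log10(p_in[sl].mean() / p_out[sl].mean())
        assert atten >= 20.0

    def test_band_above_nyquist_rejected(self):
        rec, cluster, _ = self._cluster_rec(f_p=8.0, fs=500.0)
        cluster.f_p = 260.0
        with pytest.raises(ValueError):
            iw.phase_timeseries(rec, cluster)


class TestSubclusters:
    def _cluster(self, names):
        return OscillationCluster(cluster_id="c", subject_id="s",
                                  hemisphere="left", band="theta",
                                  members=names, f_p=7.0)

    def test_mutually_close_electrodes_share_membership(self):
        elec = pd.DataFrame({"name": ["a", "b", "c", "d"],
                             "x": [0.0, 5.0, 0.0, 5.0],
                             "y": [0.0, 0.0, 5.0, 5.0], "z": 0.0,
                             "hemisphere": "left", "subject": "s"})
        subs = iw.make_subclusters(self._cluster(["a", "b", "c", "d"]), elec)
        assert len(subs) == 4
        for sc in subs:
            assert sorted(sc.members) == ["a", "b", "c", "d"]

    def test_isolated_candidate_dropped(self):
        elec = pd.DataFrame({"name": ["a", "b", "c", "d", "e"],
                             "x": [0.0, 5.0, 0.0, 5.0, 40.0],
                             "y": [0.0, 0.0, 5.0, 5.0, 0.0], "z": 0.0,
                             "hemisphere": "left", "subject": "s"})
        subs = iw.make_subclusters(self._cluster(list(elec["name"])), elec)
        assert all(sc.center != "e" for sc in subs)
        assert len(subs) == 4

    def test_projection_preserves_coplanar_distances(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(-8, 8, (5, 2))
        basis = np.linalg.qr(rng.standard_normal((3, 2)))[0].T
        coords = xy @ basis
        elec = pd.DataFrame({"name": [f"e{i}" for i in range(5)],
                             "x": coords[:, 0], "y": coords[:, 1],
                             "z": coords[:, 2],
                             "hemisphere": "left", "subject": "s"})
        subs = iw.make_subclusters(self._cluster(list(elec["name"])), elec)
        from scipy.spatial.distance import pdist
        for sc in subs:
            np.testing.assert_allclose(pdist(sc.xy), pdist(coords[sc.member_idx]),
                                       atol=1e-9)


class TestSpatialShuffle:
    def _field(self, phases, times=None):
        n, T = phases.shape
        return iw.PhaseField(cluster_id="c", f_p=8.0,
                             times=times if times is not None
                             else np.arange(T) / 100.0,
                             electrodes=[f"e{i}" for i in range(n)],
                             phases=phases, amplitude=np.ones_like(phases),
                             sample_mask=np.ones(T, dtype=bool))

    def _geometry(self, n=8, seed=5):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(-9, 9, (n, 2))
        coords = np.column_stack([xy, np.zeros(n)])
        elec = pd.DataFrame({"name": [f"e{i}" for i in range(n)],
                             "x": coords[:, 0], "y": coords[:, 1],
                             "z": coords[:, 2], "hemisphere": "left",
                             "subject": "s"})
        cluster = OscillationCluster(cluster_id="c", subject_id="s",
                                     hemisphere="left", band="theta",
                                     members=list(elec["name"]), f_p=8.0)
        return iw.make_subclusters(cluster, elec), xy

    def test_perfect_wave_attains_minimum_p(self):
        """A noiseless grid-representable plane wave fits exactly; no
        coordinate shuffle can beat it, so p hits the +1-corrected
        minimum 1/(n_perm+1)."""
        rng = np.random.default_rng(5)
        xy = rng.uniform(-9, 9, (8, 2))
        sub = iw.Subcluster(center="e0",
                            members=[f"e{i}" for i in range(8)],
                            member_idx=np.arange(8), xy=xy)
        T = 10
        drift = np.linspace(0, 90, T)
        phases = np.stack([plane_phases(xy, 90.0, 6.0, d) for d in drift],
                          axis=1)
        res = iw.spatial_shuffle_test(self._field(phases), [sub],
                                      np.arange(T), n_perm=199, seed=1)
        assert res["p_cluster"] == pytest.approx(1.0 / 200.0)
        assert res["mean_strength"] == pytest.approx(1.0, abs=1e-9)

    def test_p_strictly_positive(self):
        subs, xy = self._geometry()
        rng = np.random.default_rng(2)
        phases = rng.uniform(0, 360, (8, 10))
        res = iw.spatial_shuffle_test(self._field(phases), subs,
                                      np.arange(10), n_perm=100, seed=3)
        assert 0.0 < res["p_cluster"] <= 1.0

    def test_minimum_permutations_enforced(self):
        subs, xy = self._geometry()
        phases = np.zeros((8, 5))
        with pytest.raises(ValueError):
            iw.spatial_shuffle_test(self._field(phases), subs,
                                    np.arange(5), n_perm=50)


class TestSummarize:
    def _fit(self, T, strength=1.0):
        per_sub = [{
            "alpha": np.full(T, 90.0), "xi": np.full(T, 5.0),
            "a": np.zeros(T), "b": np.zeros(T), "rbar": np.ones(T),
            "theta": np.zeros(T), "rho_cc": np.ones(T),
            "wave_strength": np.full(T, strength), "n": 6, "k": 3}]
        return {"per_sub": per_sub, "strength": np.full(T, strength)}

    def test_all_significant_prevalence_one(self):
        s = iw.summarize_waves("c", 8.0, np.arange(10) / 50.0, self._fit(10),
                               np.ones(10, dtype=bool))
        assert s.prevalence == 1.0
        assert s.median_speed == pytest.approx(iw.wave_speed(5.0, 8.0))
        assert s.direction_hist.sum() == 10

    def test_none_significant_empty_speeds(self):
        s = iw.summarize_waves("c", 8.0, np.arange(10) / 50.0, self._fit(10),
                               np.zeros(10, dtype=bool))
        assert s.prevalence == 0.0
        assert s.speeds.size == 0
        assert np.isnan(s.median_speed)
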