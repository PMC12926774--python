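import numpy as np
import pytest

from spinalcompcor import (MaskVolume, PhysioTrace, RegressorTable,
                           VolumeSeries, assemble_design, cardiac_phase,
                           csf_regressor, detect_peaks, respiratory_phase,
                           retroicor_regressors, simulate_physio)
from spinalcompcor.nuisance import RetroicorBasis


def sinusoid_trace(period_s=1.0, duration_s=60.0, fs=100.0):
    t = np.arange(int(duration_s * fs)) / fs
    return PhysioTrace(np.sin(2 * np.pi * t / period_s), fs, 0.0, "pulse")


class TestDetectPeaks:
    def test_sinusoid_peaks_spaced_by_period(self):
        trace = sinusoid_trace(period_s=1.0)
        peaks = detect_peaks(trace, min_interval_s=0.4)
        spacing = np.diff(peaks)
        assert np.all(np.abs(spacing - 1.0) <= 1.0 / trace.fs_hz + 1e-9)

    def test_simulated_beats_all_recovered(self):
        pulse, _, truth = simulate_physio(120.0, fs_hz=100, hr_bpm=66,
                                          jitter=0.05, seed=4)
        peaks = detect_peaks(pulse, min_interval_s=0.4)
        true_t = truth["beat_times"]
        interior = true_t[(true_t > 1) & (true_t < 119)]
        for bt in interior:
            assert np.min(np.abs(peaks - bt)) <= 0.02
        # no extra peaks between beats
        assert len(peaks) <= len(true_t) + 2

    def test_constant_trace_yields_no_peaks(self):
        trace = PhysioTrace(np.ones(2000), 100.0, 0.0, "pulse")
        with pytest.warns(UserWarning):
            peaks = detect_peaks(trace, min_interval_s=0.4)
        assert peaks.size == 0


class TestCardiacPhase:
    def test_definition_at_and_between_peaks(self):
        peaks = np.array([0.0, 1.0, 2.0, 3.0])
        phi = cardiac_phase(peaks, np.array([1.0, 1.5]))
        assert phi[0] == pytest.approx(0.0)
        assert phi[1] == pytest.approx(np.pi)

    def test_constant_period_closed_form(self):
        P = 0.9
        peaks = np.arange(0, 30, P)
        t = np.linspace(0.0, peaks[-1] - 1e-6, 200)
        phi = cardiac_phase(peaks, t)
        expected = (2 * np.pi * t / P) % (2 * np.pi)
        # piecewise-linear interpolation between float peaks
        err = np.abs(np.angle(np.exp(1j * (phi - expected))))
        assert err.max() < 1e-8

    def test_extrapolation_outside_span(self):
        peaks = np.array([10.0, 11.0, 12.0])
        phi = cardiac_phase(peaks, np.array([9.5, 12.5]))
        assert phi[0] == pytest.approx(np.pi)
        assert phi[1] == pytest.approx(np.pi)
        with pytest.raises(ValueError):
            cardiac_phase(np.array([1.0]), np.array([0.5]))


class TestRespiratoryPhase:
    def test_extremes_of_the_histogram(self):
        t = np.arange(6000) / 100.0
        belt = PhysioTrace(np.sin(2 * np.pi * t / 4.0), 100.0, 0.0,
                           "respiratory")
        # at the rising maximum the cumulative fraction is ~1
        phi = respiratory_phase(belt, np.array([0.99]))  # near max, rising
        assert phi[0] > 0.9 * np.pi
        # at the global minimum the cumulative fraction is ~0
        phi_min = respiratory_phase(belt, np.array([3.0]))
        assert abs(phi_min[0]) < 0.1 * np.pi

    def test_triangular_wave_gives_linear_phase(self):
        t = np.arange(8000) / 100.0
        tri = 2 * np.abs((t / 8.0) % 1 - 0.5)  # uniform histogram
        belt = PhysioTrace(tri, 100.0, 0.0, "respiratory")
        sample_t = np.linspace(12.05, 15.9, 40)  # one rising ramp: 12..16 s
        phi = respiratory_phase(belt, sample_t)
        amp = np.interp(sample_t, t, tri)
        expected = np.pi * amp  # uniform histogram: cdf == amplitude
        assert np.all(phi > 0)
        np.testing.assert_allclose(phi, expected, atol=np.pi * 0.05)

    def test_constant_belt_rejected(self):
        belt = PhysioTrace(np.ones(1000), 100.0, 0.0, "respiratory")
        with pytest.raises(ValueError):
            respiratory_phase(belt, np.array([1.0]))


class TestRetroicor:
    def test_column_counts_scale_with_order(self):
        phi = np.linspace(0, 10, 50)
        assert len(retroicor_regressors(phi, phi, order=4)) == 16
        assert len(retroicor_regressors(phi, phi, order=1)) == 4
        t = retroicor_regressors(phi, phi, order=4)
        assert sum(c.startswith("card") for c in t.names) == 8
        assert sum(c.startswith("resp") for c in t.names) == 8

    def test_constant_heart_period_gives_pure_sinusoids(self):
        P, tr, T = 0.8, 2.0, 100
        peaks = np.arange(0.0, 300.0, P)
        vol_t = np.arange(T) * tr
        phi_c = cardiac_phase(peaks, vol_t)
        table = retroicor_regressors(phi_c, np.zeros(T), order=4)
        for k in range(1, 5):
            np.testing.assert_allclose(
                table.data[f"card_cos{k}"], np.cos(2 * np.pi * k * vol_t / P),
                atol=1e-8)
            np.testing.assert_allclose(
                table.data[f"card_sin{k}"], np.sin(2 * np.pi * k * vol_t / P),
                atol=1e-8)

    def test_slice_resolved_basis(self):
        data = np.zeros((4, 4, 3, 20)) + np.arange(20)
        vol = VolumeSeries(data, (1, 1, 3), 2.0,
                           slice_times_s=[0.0, 0.5, 1.0])
        pulse, belt, _ = simulate_physio(50.0, seed=0)
        peaks = detect_peaks(pulse, 0.4)
        basis = RetroicorBasis.from_traces(vol, peaks, belt, order=4)
        assert basis.phi_c.shape == (3, 20)
        assert len(basis.for_slice(1)) == 16
        assert not np.allclose(basis.phi_c[0], basis.phi_c[1])


class TestCsfRegressor:
    def make_vol(self, series_by_voxel):
        n = len(series_by_voxel)
        T = len(series_by_voxel[0])
        data = np.zeros((n, 1, 1, T))
        for i, s in enumerate(series_by_voxel):
            data[i, 0, 0, :] = s
        mask = MaskVolume(np.ones((n, 1, 1), dtype=np.uint8), (1, 1, 3))
        return VolumeSeries(data, (1, 1, 3), 2.0), mask

    def test_top_variance_voxel_selected(self, rng):
        base = rng.standard_normal(30)
        series = [i * base + rng.standard_normal(30) * 0.01
                  for i in (1, 2, 3, 4, 100)]
        vol, mask = self.make_vol(series)
        reg = csf_regressor(vol, mask, 0, top_fraction=0.2)
        np.testing.assert_allclose(reg.values()[:, 0], series[4])

    def test_count_is_ceil_of_fraction(self, rng):
        series = [rng.standard_normal(20) for _ in range(100)]
        vol, mask = self.make_vol(series)
        variances = np.array([np.var(s, ddof=1) for s in series])
        top20 = np.argsort(-variances, kind="stable")[:20]
        expected = np.mean([series[i] for i in top20], axis=0)
        reg = csf_regressor(vol, mask, 0, top_fraction=0.2)
        np.testing.assert_allclose(reg.values()[:, 0], expected)

    def test_single_voxel_slice(self, rng):
        series = [rng.standard_normal(20)]
        vol, mask = self.make_vol(series)
        reg = csf_regressor(vol, mask, 0)
        np.testing.assert_allclose(reg.values()[:, 0], series[0])


class TestAssembleDesign:
    @staticmethod
    def tables(rng, T=50, k_pca=9):
        mk = lambda n, g, p: RegressorTable(
            {f"{p}{i}": rng.standard_normal(T) for i in range(n)},
            {f"{p}{i}": g for i in range(n)})
        return dict(task=mk(1, "task", "task"),
                    motion=mk(2, "motion", "mo"),
                    csf=mk(1, "csf", "csf"),
                    retro=mk(16, "retro", "re"),
                    pca=mk(k_pca, "pca", "pc"))

    def test_base_has_19_nuisance_regressors(self, rng):
        t = self.tables(rng)
        d = assemble_design(t["task"], t["motion"], t["csf"], t["retro"],
                            None, "base")
        assert d.nuisance_count == 19
        assert d.task_columns == ["task0"]

    def test_extended_and_spinalcompcor_counts(self, rng):
        t = self.tables(rng, k_pca=9)
        ext = assemble_design(**t, model_kind="extended")
        assert ext.nuisance_count == 28
        scc = assemble_design(t["task"], t["motion"], t["csf"], None,
                              t["pca"], "spinalcompcor")
        assert scc.nuisance_count == 12
        assert not scc.regressors.columns_in_group("retro")

    def test_missing_groups_rejected(self, rng):
        t = self.tables(rng)
        with pytest.raises(ValueError):
            assemble_design(t["task"], t["motion"], t["csf"], t["retro"],
                            None, "extended")
        with pytest.raises(ValueError):
            assemble_design(t["task"], t["motion"], t["csf"], None,
                            t["pca"], "base")

    def test_nuisance_columns_demeaned(self, rng):
        t = self.tables(rng)
        d = assemble_design(**t, model_kind="extended")
        nuis = d.regressors.data[d.nuisance_columns].to_numpy()
        np.testing.assert_allclose(nuis.mean(axis=0), 0, atol=1e-12)
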