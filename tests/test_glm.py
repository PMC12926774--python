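import numpy as np
import pytest
from scipy import stats

from spinalcompcor import (MaskVolume, RegressorTable, VolumeSeries,
                           fit_glm, highpass_filter, nested_f_test,
                           omnibus_f_test, significant_proportion)
from spinalcompcor.glm import dct_highpass_basis
from spinalcompcor.nuisance import DesignMatrix


def make_design(columns: dict, groups: dict, kind="base"):
    return DesignMatrix(RegressorTable(columns, groups), kind)


def volume_from_matrix(Y, tr=2.0):
    """(T, nvox) data as a (nvox, 1, 1, T) volume with an all-ones mask."""
    T, n = Y.shape
    data = np.transpose(Y)[:, None, None, :]
    vol = VolumeSeries(data, (1, 1, 3), tr)
    mask = MaskVolume(np.ones((n, 1, 1), dtype=np.uint8), (1, 1, 3))
    return vol, mask


class TestHighpass:
    def test_constant_removed(self):
        out = highpass_filter(np.full(100, 7.0), tr_s=2.0, cutoff_s=100)
        np.testing.assert_allclose(out, 0, atol=1e-10)

    def test_slow_sinusoid_suppressed_fast_passed(self):
        T, tr = 300, 2.0
        t = np.arange(T) * tr
        slow = np.sin(2 * np.pi * t / 200.0)
        fast = np.sin(2 * np.pi * t / 20.0)
        out_slow = highpass_filter(slow, tr, 100.0)
        out_fast = highpass_filter(fast, tr, 100.0)
        assert np.sum(out_slow ** 2) < 0.10 * np.sum(slow ** 2)
        assert np.sum(out_fast ** 2) > 0.95 * np.sum(fast ** 2)

    def test_matches_explicit_projection_oracle(self, rng):
        T, tr, cutoff = 120, 2.0, 100.0
        x = rng.standard_normal(T)
        B = dct_highpass_basis(T, tr, cutoff)
        expected = x - B @ np.linalg.lstsq(B, x, rcond=None)[0]
        np.testing.assert_allclose(highpass_filter(x, tr, cutoff),
                                   expected, atol=1e-10)

    def test_cutoff_guards(self):
        with pytest.raises(ValueError):
            dct_highpass_basis(100, 2.0, 3.0)
        with pytest.raises(ValueError):
            dct_highpass_basis(6, 2.0, 4.1)


class TestFitGlm:
    def test_data_in_design_span_fits_perfectly(self, rng):
        T = 60
        x = rng.standard_normal(T)
        Y = np.outer(x, [1.0, -2.0, 0.5])
        vol, mask = volume_from_matrix(Y)
        d = make_design({"x": x}, {"x": "task"})
        res = fit_glm(vol, d, mask, hp_cutoff_s=None)
        assert np.all(res.rss < 1e-16 * np.sum(Y ** 2))

    def test_single_regressor_closed_form(self, rng):
        T = 80
        x = rng.standard_normal(T)
        y = 2.0 * x + rng.standard_normal(T)
        vol, mask = volume_from_matrix(y[:, None])
        d = make_design({"x": x}, {"x": "task"})
        res = fit_glm(vol, d, mask, hp_cutoff_s=None)
        expected = float(x @ y) / float(x @ x)
        assert res.betas[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_voxels_outside_mask_absent(self, rng):
        Y = rng.standard_normal((40, 5))
        vol, mask = volume_from_matrix(Y)
        mask.data[3:, 0, 0] = False
        d = make_design({"x": rng.standard_normal(40)}, {"x": "task"})
        res = fit_glm(vol, d, mask)
        assert res.n_voxels == 3
        assert set(map(tuple, res.coords[:, :1].tolist())) == {(0,), (1,),
                                                               (2,)}

    def test_filter_commutes_with_confound_regression(self, rng):
        """Filtering both sides equals adding the filter basis to an
        unfiltered model."""
        T, tr, cutoff = 100, 2.0, 100.0
        x = rng.standard_normal(T)
        Y = rng.standard_normal((T, 4))
        vol, mask = volume_from_matrix(Y, tr)
        d = make_design({"x": x}, {"x": "task"})
        filtered = fit_glm(vol, d, mask, hp_cutoff_s=cutoff)
        B = dct_highpass_basis(T, tr, cutoff)
        cols = {"x": x}
        groups = {"x": "task"}
        for j in range(B.shape[1]):
            cols[f"b{j}"] = B[:, j]
            groups[f"b{j}"] = "other"
        aug = fit_glm(vol, make_design(cols, groups), mask, hp_cutoff_s=None)
        np.testing.assert_allclose(filtered.rss, aug.rss, rtol=1e-8,
                                   atol=1e-10)
        assert filtered.residual_dof == aug.n_timepoints - aug.design_rank

    def test_rss_never_increases_with_added_regressors(self, rng):
        T = 60
        Y = rng.standard_normal((T, 30))
        vol, mask = volume_from_matrix(Y)
        x1, x2 = rng.standard_normal(T), rng.standard_normal(T)
        small = fit_glm(vol, make_design({"a": x1}, {"a": "task"}), mask)
        big = fit_glm(vol, make_design({"a": x1, "b": x2},
                                       {"a": "task", "b": "motion"}), mask)
        assert np.all(big.rss <= small.rss + 1e-10)

    def test_ar1_prewhitening_runs_and_reduces_autocorr(self, rng):
        T = 120
        e = np.zeros((T, 10))
        w = rng.standard_normal((T, 10))
        for t in range(1, T):
            e[t] = 0.5 * e[t - 1] + w[t]
        vol, mask = volume_from_matrix(e)
        d = make_design({"x": rng.standard_normal(T)}, {"x": "task"})
        res = fit_glm(vol, d, mask, prewhiten="ar1", hp_cutoff_s=None)
        r = res.residuals
        lag1 = np.mean([np.corrcoef(r[i, :-1], r[i, 1:])[0, 1]
                        for i in range(10)])
        assert abs(lag1) < 0.3


class TestNestedF:
    @staticmethod
    def two_fit_oracle(X_full, X_red, y):
        bf, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        br, *_ = np.linalg.lstsq(X_red, y, rcond=None)
        rss_f = np.sum((y - X_full @ bf) ** 2)
        rss_r = np.sum((y - X_red @ br) ** 2)
        df_num = X_full.shape[1] - X_red.shape[1]
        df_den = len(y) - X_full.shape[1]
        return ((rss_r - rss_f) / df_num) / (rss_f / df_den)

    def test_tiny_case_matches_two_fit_oracle(self, rng):
        T = 8
        x1, x2 = rng.standard_normal(T), rng.standard_normal(T)
        y = x1 + 0.5 * x2 + rng.standard_normal(T)
        vol, mask = volume_from_matrix(y[:, None])
        full = fit_glm(vol, make_design({"a": x1, "b": x2},
                                        {"a": "task", "b": "retro"}),
                       mask, hp_cutoff_s=None)
        red = fit_glm(vol, make_design({"a": x1}, {"a": "task"}), mask,
                      hp_cutoff_s=None)
        ft = nested_f_test(full, red)
        expected = self.two_fit_oracle(np.column_stack([x1, x2]),
                                       x1[:, None], y)
        assert ft.F[0] == pytest.approx(expected, abs=1e-10)
        assert (ft.df_num, ft.df_den) == (1, T - 2)

    def test_identical_designs_rejected(self, rng):
        T = 20
        x = rng.standard_normal(T)
        vol, mask = volume_from_matrix(rng.standard_normal((T, 3)))
        a = fit_glm(vol, make_design({"x": x}, {"x": "task"}), mask)
        with pytest.raises(ValueError):
            nested_f_test(a, a)

    def test_orthogonal_added_column_gives_zero_F(self, rng):
        T = 40
        x = rng.standard_normal(T)
        y = x + rng.standard_normal(T)
        extra = rng.standard_normal(T)
        # orthogonal to both the data and the existing regressor, so the
        # added column absorbs exactly nothing
        A = np.column_stack([x, y])
        extra -= A @ np.linalg.lstsq(A, extra, rcond=None)[0]
        vol, mask = volume_from_matrix(y[:, None])
        full = fit_glm(vol, make_design({"a": x, "b": extra},
                                        {"a": "task", "b": "retro"}),
                       mask, hp_cutoff_s=None)
        red = fit_glm(vol, make_design({"a": x}, {"a": "task"}), mask,
                      hp_cutoff_s=None)
        ft = nested_f_test(full, red)
        assert ft.F[0] == pytest.approx(0.0, abs=1e-8)
        assert ft.p[0] == pytest.approx(1.0, abs=1e-8)

    def test_null_p_values_uniform(self, rng):
        """Type-I calibration: white-noise data, nested p ~ Uniform(0,1)."""
        T, n = 50, 10_000
        Y = rng.standard_normal((T, n))
        vol, mask = volume_from_matrix(Y)
        x1, x2 = rng.standard_normal(T), rng.standard_normal(T)
        full = fit_glm(vol, make_design({"a": x1, "b": x2},
                                        {"a": "task", "b": "retro"}),
                       mask, hp_cutoff_s=None)
        red = fit_glm(vol, make_design({"a": x1}, {"a": "task"}), mask,
                      hp_cutoff_s=None)
        ft = nested_f_test(full, red)
        ks = stats.kstest(ft.p, "uniform")
        assert ks.pvalue > 0.01

    def test_z_monotone_in_F(self, rng):
        T = 30
        x1, x2 = rng.standard_normal(T), rng.standard_normal(T)
        Y = rng.standard_normal((T, 200))
        vol, mask = volume_from_matrix(Y)
        full = fit_glm(vol, make_design({"a": x1, "b": x2},
                                        {"a": "task", "b": "retro"}),
                       mask, hp_cutoff_s=None)
        red = fit_glm(vol, make_design({"a": x1}, {"a": "task"}), mask,
                      hp_cutoff_s=None)
        ft = nested_f_test(full, red)
        order = np.argsort(ft.F)
        assert np.all(np.diff(ft.z[order]) >= -1e-12)
        assert np.all(np.isfinite(ft.z))


class TestOmnibusF:
    def test_equals_nested_test_dropping_group(self, rng):
        T = 40
        cols = {"task": rng.standard_normal(T)}
        groups = {"task": "task"}
        for i in range(4):
            cols[f"r{i}"] = rng.standard_normal(T)
            groups[f"r{i}"] = "retro"
        Y = rng.standard_normal((T, 6))
        vol, mask = volume_from_matrix(Y)
        full = fit_glm(vol, make_design(cols, groups), mask)
        red = fit_glm(vol, make_design({"task": cols["task"]},
                                       {"task": "task"}), mask)
        omni = omnibus_f_test(full, "retro")
        nested = nested_f_test(full, red)
        np.testing.assert_allclose(omni.F, nested.F, atol=1e-10)
        assert omni.df_num == 4

    def test_empty_group_rejected(self, rng):
        T = 30
        vol, mask = volume_from_matrix(rng.standard_normal((T, 3)))
        g = fit_glm(vol, make_design({"x": rng.standard_normal(T)},
                                     {"x": "task"}), mask)
        with pytest.raises(ValueError):
            omnibus_f_test(g, "pca")


class TestSignificantProportion:
    def test_all_p_one_gives_zero(self, rng):
        T = 40
        x = rng.standard_normal(T)
        y = x.copy()
        extra = rng.standard_normal(T)
        extra -= extra @ y / (y @ y) * y
        vol, mask = volume_from_matrix(np.column_stack([y, y, y]))
        full = fit_glm(vol, make_design({"a": x, "b": extra},
                                        {"a": "task", "b": "retro"}),
                       mask, hp_cutoff_s=None)
        red = fit_glm(vol, make_design({"a": x}, {"a": "task"}), mask,
                      hp_cutoff_s=None)
        ft = nested_f_test(full, red)
        prop, med = significant_proportion(ft, mask)
        assert prop == 0.0

    def test_single_voxel_roi_median(self, rng):
        T = 30
        x1, x2 = rng.standard_normal(T), rng.standard_normal(T)
        Y = rng.standard_normal((T, 5))
        vol, mask = volume_from_matrix(Y)
        full = fit_glm(vol, make_design({"a": x1, "b": x2},
                                        {"a": "task", "b": "retro"}), mask)
        red = fit_glm(vol, make_design({"a": x1}, {"a": "task"}), mask)
        ft = nested_f_test(full, red)
        roi = MaskVolume(np.zeros((5, 1, 1), dtype=np.uint8), (1, 1, 3))
        roi.data[2, 0, 0] = True
        prop, med = significant_proportion(ft, roi)
        assert med == pytest.approx(ft.F[2])
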