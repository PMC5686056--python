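"""Curve reconstruction, integrals, model fits and the six features."""

import numpy as np
import pytest

from dcehabitat.io_core import MaskVolume, TimeGrid
from dcehabitat.kinetics import (
    FEATURE_NAMES,
    SignalCurve,
    auc,
    aufc,
    feature_set,
    fit_biexp,
    fit_late_linear,
    mean_raw_curve,
    reconstruct_curve,
)
from dcehabitat.phantom import (
    DEFAULT_KINETICS,
    LESION_GRADES,
    TissueKinetics,
    kinetic_curve,
)


def _curve_from(kin: TissueKinetics, grid: TimeGrid) -> SignalCurve:
    """Baseline-corrected noiseless curve of a tissue preset."""
    return SignalCurve(kinetic_curve(kin, grid) - kin.s0, grid)


class TestReconstructCurve:
    def test_exact_factorization_reconstruction(self, exact_factorization):
        from dcehabitat.decomposition import run_nmf

        cm, W0, S0 = exact_factorization
        res = run_nmf(cm, k=3)
        mask = np.zeros(cm.shape, dtype=bool)
        mask[tuple(cm.coords[:100].T)] = True
        curve = reconstruct_curve(res, MaskVolume(mask, "ROI"))
        expected = cm.D[:100].mean(axis=0)
        np.testing.assert_allclose(curve.values, expected, atol=1e-6 * cm.D.max())

    def test_single_voxel_mask(self, exact_factorization):
        from dcehabitat.decomposition import run_nmf

        cm, _, _ = exact_factorization
        res = run_nmf(cm, k=3)
        mask = np.zeros(cm.shape, dtype=bool)
        mask[tuple(cm.coords[:1].T)] = True
        curve = reconstruct_curve(res, MaskVolume(mask, "ROI"))
        np.testing.assert_allclose(
            curve.values, res.W[0] @ res.S, rtol=1e-12
        )

    def test_identical_weights_mean_invariance(self, grid):
        from dcehabitat.decomposition import NmfResult

        W = np.tile([2.0, 1.0, 0.5], (5, 1))
        S = np.random.default_rng(0).random((3, 12))
        res = NmfResult(
            W=W,
            S=S,
            coords=np.argwhere(np.ones((5, 1, 1), bool)),
            shape=(5, 1, 1),
            grid=grid,
            residual=0.0,
        )
        full = np.ones((5, 1, 1), dtype=bool)
        one = np.zeros((5, 1, 1), dtype=bool)
        one[0] = True
        np.testing.assert_allclose(
            reconstruct_curve(res, MaskVolume(full, "ROI")).values,
            reconstruct_curve(res, MaskVolume(one, "ROI")).values,
        )

    def test_empty_mask_rejected(self, nmf_noiseless):
        with pytest.raises(ValueError):
            reconstruct_curve(
                nmf_noiseless,
                MaskVolume(np.zeros(nmf_noiseless.shape, bool), "ROI"),
            )


class TestMeanRawCurve:
    def test_constant_region_gives_zero(self, grid):
        from dcehabitat.io_core import DceSeries

        data = np.full((2, 2, 1, 12), 33.0)
        series = DceSeries(data=data, spacing=(1.25, 1.25, 2.5), grid=grid)
        curve = mean_raw_curve(series, MaskVolume(np.ones((2, 2, 1), bool)))
        np.testing.assert_array_equal(curve.values, np.zeros(12))

    def test_opposite_deviations_average_to_zero(self, grid):
        from dcehabitat.io_core import DceSeries

        rng = np.random.default_rng(1)
        c = rng.uniform(50, 100, 12)
        baseline = c[:2].mean()
        data = np.stack([c, -c + 2 * baseline]).reshape(2, 1, 1, 12)
        series = DceSeries(data=data, spacing=(1.25, 1.25, 2.5), grid=grid)
        curve = mean_raw_curve(series, MaskVolume(np.ones((2, 1, 1), bool)))
        np.testing.assert_allclose(curve.values, np.zeros(12), atol=1e-9)

    def test_phantom_muscle_equals_kinetic_curve(self, noiseless_phantom):
        series, truth = noiseless_phantom
        curve = mean_raw_curve(series, truth.masks["GM"])
        kin = DEFAULT_KINETICS["muscle"]
        expected = kinetic_curve(kin, series.grid) - kin.s0
        np.testing.assert_allclose(curve.values, expected, atol=1e-9)


class TestAuc:
    def test_rectangle(self, grid):
        curve = SignalCurve(np.ones(12), grid)
        assert auc(curve, 60, 120) == pytest.approx(60.0)

    def test_linear_ramp_closed_form(self, grid):
        curve = SignalCurve(grid.times / 330.0, grid)
        # integral of t/330 over [240, 330]
        expected = (330.0**2 - 240.0**2) / (2 * 330.0)
        assert auc(curve, 240, 330) == pytest.approx(expected)

    def test_interpolated_endpoints_match_dense_oracle(self, grid):
        rng = np.random.default_rng(2)
        curve = SignalCurve(rng.uniform(0, 10, 12), grid)
        t_dense = np.linspace(45.0, 315.0, 270001)
        dense = np.interp(t_dense, grid.times, curve.values)
        oracle = np.trapezoid(dense, t_dense)
        assert auc(curve, 45.0, 315.0) == pytest.approx(oracle, abs=1e-6)
        # frame-aligned window agrees to machine precision with trapezoid
        sel = (grid.times >= 60) & (grid.times <= 120)
        exact = np.trapezoid(curve.values[sel], grid.times[sel])
        assert auc(curve, 60, 120) == pytest.approx(exact, abs=1e-9)

    def test_window_outside_grid_rejected(self, grid):
        curve = SignalCurve(np.ones(12), grid)
        with pytest.raises(ValueError):
            auc(curve, 300, 400)


class TestFitBiexp:
    @pytest.mark.parametrize("grade", LESION_GRADES)
    def test_noiseless_round_trip(self, grade, grid):
        kin = DEFAULT_KINETICS[f"lesion_{grade}"]
        p = fit_biexp(_curve_from(kin, grid))
        assert p.sm == pytest.approx(kin.sm - kin.s0, rel=0.02)
        assert p.tau == pytest.approx(kin.tau, rel=0.02)
        assert abs(p.s0) <= 0.02 * (kin.sm - kin.s0)

    def test_plateau_has_no_washout(self):
        grid = TimeGrid.default()
        kin = TissueKinetics(s0=0.0, amplitude=100.0, k1=0.05, k2=0.0, t0=30.0)
        curve = SignalCurve(kinetic_curve(kin, grid), grid)
        p = fit_biexp(curve)
        assert abs(p.wo_biexp) < 1e-3 * p.sm

    def test_scale_equivariance(self, grid):
        kin = DEFAULT_KINETICS["lesion_4+3"]
        c1 = _curve_from(kin, grid)
        c2 = SignalCurve(2.0 * c1.values, grid)
        p1, p2 = fit_biexp(c1), fit_biexp(c2)
        assert p2.sm == pytest.approx(2 * p1.sm, rel=1e-3)
        assert p2.wo_biexp == pytest.approx(2 * p1.wo_biexp, rel=1e-2)
        assert p2.tau == pytest.approx(p1.tau, rel=1e-3)
        assert p2.t0 == pytest.approx(p1.t0, abs=0.5)

    def test_end_slope_washout_variant(self, grid):
        kin = DEFAULT_KINETICS["lesion_8"]
        c = _curve_from(kin, grid)
        mean_wo = fit_biexp(c).wo_biexp
        end_wo = fit_biexp(c, washout_slope="end").wo_biexp
        # both positive under washout; the decay flattens with time, so
        # the instantaneous end slope is shallower than the peak-to-end mean
        assert end_wo > 0 and mean_wo > 0
        assert end_wo < mean_wo

    def test_non_enhancing_curve_rejected(self, grid):
        with pytest.raises(ValueError):
            fit_biexp(SignalCurve(np.linspace(10, 0, 12), grid))

    def test_noisy_tau_recovery_median(self, grid):
        from dcehabitat.phantom import noise_sigma_for_snr

        kin = DEFAULT_KINETICS["lesion_3+4"]
        clean = kinetic_curve(kin, grid) - kin.s0
        sigma = noise_sigma_for_snr(kin, 20)
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(30):
            noisy = clean + rng.normal(0, sigma, 12)
            p = fit_biexp(SignalCurve(noisy, grid))
            errs.append(abs(p.tau - kin.tau) / kin.tau)
        assert np.median(errs) <= 0.10


class TestAufc:
    def test_flat_fit_rectangle(self):
        from dcehabitat.kinetics import BiexpParams

        p = BiexpParams(
            s0=3.0, sm=3.0, t0=0.0, tau=np.inf, wo_biexp=0.0,
            A=0.0, k1=0.01, k2=0.0, rmse=0.0,
        )
        assert aufc(p, 60, 120) == pytest.approx(60 * 3.0, rel=1e-9)

    def test_matches_analytic_integral(self, grid):
        kin = DEFAULT_KINETICS["lesion_8"]
        p = fit_biexp(_curve_from(kin, grid))
        t1, t2 = 60.0, 120.0

        def analytic(pp, t1, t2):
            # integral of s0 + A(e^{-k2 d} - e^{-k1 d}), d = t - t0, t > t0
            a = max(t1 - pp.t0, 0.0)
            b = max(t2 - pp.t0, 0.0)
            ex = lambda k, d: (1 - np.exp(-k * d)) / k
            return pp.s0 * (t2 - t1) + pp.A * (
                (ex(pp.k2, b) - ex(pp.k2, a)) - (ex(pp.k1, b) - ex(pp.k1, a))
            )

        assert aufc(p, t1, t2) == pytest.approx(analytic(p, t1, t2), rel=1e-4)

    def test_additive_over_abutting_windows(self, grid):
        kin = DEFAULT_KINETICS["lesion_6"]
        p = fit_biexp(_curve_from(kin, grid))
        total = aufc(p, 60, 330)
        parts = aufc(p, 60, 120) + aufc(p, 120, 240) + aufc(p, 240, 330)
        assert parts == pytest.approx(total, rel=1e-9)


class TestLateLinear:
    def test_exact_line(self):
        grid = TimeGrid(times=np.array([0.0, 270.0, 300.0, 330.0]), n_pre=1)
        curve = SignalCurve(np.array([0.0, 10.0, 9.0, 8.0]), grid)
        fit = fit_late_linear(curve)
        assert fit.wo_linear == pytest.approx(-1.0 / 30.0)

    def test_flat_tail(self, grid):
        curve = SignalCurve(np.full(12, 4.0), grid)
        assert fit_late_linear(curve).wo_linear == pytest.approx(0.0, abs=1e-12)

    def test_slope_estimate_unbiased(self):
        grid = TimeGrid(times=np.array([0.0, 270.0, 300.0, 330.0]), n_pre=1)
        rng = np.random.default_rng(4)
        true_slope = -0.05
        slopes = []
        for _ in range(1000):
            vals = 20.0 + true_slope * grid.times + rng.normal(0, 1.0, 4)
            slopes.append(fit_late_linear(SignalCurve(vals, grid)).wo_linear)
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - true_slope) < 4 * se

    def test_too_few_frames_rejected(self):
        grid = TimeGrid(times=np.array([0.0, 100.0, 280.0]), n_pre=1)
        with pytest.raises(ValueError):
            fit_late_linear(SignalCurve(np.zeros(3), grid))


class TestFeatureSet:
    def test_self_normalization_gives_unit_ratios(self, grid):
        kin = DEFAULT_KINETICS["lesion_3+4"]
        c = _curve_from(kin, grid)
        fs = feature_set(c, c)
        for name in FEATURE_NAMES:
            assert fs.valid[name]
            assert fs.ratio[name] == pytest.approx(1.0, rel=1e-9)

    def test_wash_in_matches_generative_slope(self, grid):
        kin = DEFAULT_KINETICS["lesion_4+3"]
        fs = feature_set(_curve_from(kin, grid))
        expected = (kin.sm - kin.s0) / kin.tau
        assert fs.raw["wash_in"] == pytest.approx(expected, rel=0.02)

    def test_all_six_ratios_increase_with_grade(self, grid):
        """The phantom's monotonicity contract on noiseless curves."""
        mus = DEFAULT_KINETICS["muscle"]
        mcurve = SignalCurve(
            kinetic_curve(mus, grid) - mus.s0, grid, "muscle_mean"
        )
        prev = None
        for g in LESION_GRADES:
            fs = feature_set(_curve_from(DEFAULT_KINETICS[f"lesion_{g}"], grid), mcurve)
            vals = np.array([fs.ratio[n] for n in FEATURE_NAMES])
            assert np.all(np.isfinite(vals))
            if prev is not None:
                assert np.all(vals > prev)
            prev = vals

    def test_ratios_invariant_to_global_scaling(self, grid):
        kin = DEFAULT_KINETICS["lesion_8"]
        mus = DEFAULT_KINETICS["muscle"]
        c = _curve_from(kin, grid)
        m = SignalCurve(kinetic_curve(mus, grid) - mus.s0, grid, "muscle_mean")
        fs1 = feature_set(c, m)
        fs2 = feature_set(
            SignalCurve(3.0 * c.values, grid),
            SignalCurve(3.0 * m.values, grid, "muscle_mean"),
        )
        for name in FEATURE_NAMES:
            assert fs2.ratio[name] == pytest.approx(fs1.ratio[name], rel=1e-3)

    def test_non_enhancing_muscle_invalidates_ratios(self, grid):
        kin = DEFAULT_KINETICS["lesion_6"]
        c = _curve_from(kin, grid)
        flat = SignalCurve(np.zeros(12), grid, "muscle_mean")
        with pytest.warns(UserWarning):
            fs = feature_set(c, flat)
        assert not any(fs.valid[n] for n in FEATURE_NAMES)
        assert np.isfinite(fs.raw["early_auc"])  # raw features still present
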