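"""Signal model, analytic initialization and segmented fitting."""

import numpy as np
import pytest

from ivim_bopt import (
    FitConfig,
    IVIMParams,
    SignalCurve,
    analytic_init,
    fit_ivim,
    fit_volume,
    ivim_signal,
)
from ivim_bopt.ivim import _sse

from conftest import random_truth


class TestSignal:
    @pytest.mark.parametrize(
        "params, b, expected",
        [
            # monoexponential limit: f=0 at b=1000 with D=1e-3 -> e^-1
            (IVIMParams(1, 0.0, 1e-3, 10e-3), 1000.0, np.exp(-1.0)),
            # identity at b=0
            (IVIMParams(2.7, 0.2, 0.8e-3, 12e-3), 0.0, 2.7),
            # direct arithmetic: 0.1 e^-2 + 0.9 e^-0.2
            (
                IVIMParams(1, 0.1, 1e-3, 10e-3),
                200.0,
                0.1 * np.exp(-2.0) + 0.9 * np.exp(-0.2),
            ),
        ],
    )
    def test_pointwise_values(self, params, b, expected):
        assert ivim_signal(params, b) == pytest.approx(expected, rel=1e-12)

    def test_non_increasing_in_b(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(0, 1500, 301)
        for _ in range(25):
            s = ivim_signal(random_truth(rng), grid)
            assert np.all(np.diff(s) <= 1e-15)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            IVIMParams(S0=1, f=1.2, D=1e-3, Dstar=1e-2)
        with pytest.raises(ValueError):
            IVIMParams(S0=1, f=0.1, D=1e-3, Dstar=0.5e-3)  # Dstar < D


class TestAnalyticInit:
    def test_monoexponential_recovers_slope_and_zero_f(self):
        b = np.array([0, 300, 400, 500, 600, 700, 800, 900], float)
        curve = SignalCurve(b, np.exp(-b * 1e-3))
        init = analytic_init(curve)
        assert init.D == pytest.approx(1e-3, rel=1e-10)
        assert init.f == pytest.approx(0.0, abs=1e-12)
        assert init.S0 == pytest.approx(1.0)

    def test_biexponential_on_full_palette(self, palette_b, gm_truth):
        curve = SignalCurve(palette_b, ivim_signal(gm_truth, palette_b))
        init = analytic_init(curve)
        assert init.D == pytest.approx(gm_truth.D, rel=0.02)
        assert init.f == pytest.approx(gm_truth.f, abs=0.01)

    def test_two_tail_points_use_two_point_slope(self):
        b = np.array([0.0, 300.0, 900.0])
        s = np.array([1.0, 0.70, 0.38])
        init = analytic_init(curve := SignalCurve(b, s))
        expected = (np.log(s[1]) - np.log(s[2])) / (b[2] - b[1])
        assert init.D == pytest.approx(expected, rel=1e-12)

    def test_requires_b0_and_enough_tail(self):
        with pytest.raises(ValueError, match="b=0"):
            analytic_init(SignalCurve([10, 300, 900], [1.0, 0.7, 0.4]))
        with pytest.raises(ValueError, match="tail"):
            analytic_init(SignalCurve([0, 10, 20], [1.0, 0.99, 0.98]))


class TestFit:
    def test_noiseless_full_palette_recovery(self, palette_b, gm_truth):
        curve = SignalCurve(palette_b, ivim_signal(gm_truth, palette_b))
        res = fit_ivim(curve)
        assert res.converged
        err = np.abs(res.params.as_array() - gm_truth.as_array())
        assert np.all(err / np.abs(gm_truth.as_array()) < 1e-3)

    def test_noiseless_recovery_randomized_truths(self, palette_b):
        rng = np.random.default_rng(12)
        for _ in range(20):
            truth = random_truth(rng)
            curve = SignalCurve(palette_b, ivim_signal(truth, palette_b))
            est = fit_ivim(curve).params.as_array()
            rel = np.abs(est - truth.as_array()) / np.abs(truth.as_array())
            assert np.max(rel) < 1e-3

    def test_three_bvalue_fit_is_the_analytic_solution(self):
        b = np.array([0.0, 200.0, 900.0])
        truth = IVIMParams(1, 0.08, 0.9e-3, 11e-3)
        curve = SignalCurve(b, ivim_signal(truth, b))
        init = analytic_init(curve)
        res = fit_ivim(curve)
        assert res.method == "analytic"
        assert res.params == init  # bit-for-bit

    def test_objective_descends_from_initialization(self, palette_b):
        rng = np.random.default_rng(3)
        truth = IVIMParams(1, 0.1, 1e-3, 10e-3)
        clean = ivim_signal(truth, palette_b)
        for _ in range(10):
            noisy = np.abs(clean + rng.normal(0, 0.02, palette_b.size))
            curve = SignalCurve(palette_b, noisy)
            init = analytic_init(curve)
            res = fit_ivim(curve)
            assert res.sse <= _sse(palette_b, noisy, init) + 1e-12

    def test_noisy_fit_matches_grid_search_oracle(self, palette_b, gm_truth):
        """Mean estimates of the two-stage fitter agree with an independent
        brute-force grid fitter within Monte-Carlo confidence bands."""
        b = palette_b
        clean = ivim_signal(gm_truth, b)
        sigma = 0.01
        rng = np.random.default_rng(42)
        n_curves = 200

        fg = np.linspace(0, 0.35, 36)
        dg = np.linspace(0.4e-3, 1.6e-3, 31)
        dsg = np.geomspace(1.5e-3, 0.1, 41)
        F, D, DS = np.meshgrid(fg, dg, dsg, indexing="ij")
        M = F[..., None] * np.exp(-b * DS[..., None]) + (1 - F[..., None]) * np.exp(
            -b * D[..., None]
        )
        MM = (M * M).sum(-1)

        two, grid = [], []
        for _ in range(n_curves):
            y = np.abs(clean + rng.normal(0, sigma, b.size))
            two.append(fit_ivim(SignalCurve(b, y)).params.as_array())
            s0_hat = (M @ y) / MM  # profiled linear amplitude
            sse = (y * y).sum() - s0_hat**2 * MM
            i = np.unravel_index(np.argmin(sse), sse.shape)
            grid.append([s0_hat[i], F[i], D[i], DS[i]])
        two, grid = np.asarray(two), np.asarray(grid)

        half_step = np.array([0.0, np.diff(fg)[0], np.diff(dg)[0], dsg[1] - dsg[0]]) / 2
        for j in range(4):
            se = np.sqrt(two[:, j].var() / n_curves + grid[:, j].var() / n_curves)
            assert abs(two[:, j].mean() - grid[:, j].mean()) <= 5 * se + half_step[j]

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_ivim(SignalCurve([0.0, 900.0], [1.0, 0.4]))


class TestFitVolume:
    def test_noiseless_volume_matches_truth_everywhere(self, palette_b):
        truth = IVIMParams(1, 0.1, 1e-3, 10e-3)
        signal = np.asarray(ivim_signal(truth, palette_b))
        image = np.tile(signal, (2, 5, 1, 1))  # 10 voxels
        mask = np.ones((2, 5, 1), bool)
        maps = fit_volume(image, palette_b, mask)
        for name, val in zip(("S0", "f", "D", "Dstar"), truth.as_array()):
            assert np.allclose(maps.get(name)[mask], val, rtol=1e-3)
        assert maps.converged[mask].all()

    def test_single_voxel_consistent_with_curve_fit(self, palette_b):
        rng = np.random.default_rng(8)
        y = np.abs(
            ivim_signal(IVIMParams(1, 0.1, 1e-3, 10e-3), palette_b)
            + rng.normal(0, 0.02, palette_b.size)
        )
        image = y.reshape(1, 1, 1, -1)
        mask = np.ones((1, 1, 1), bool)
        maps = fit_volume(image, palette_b, mask)
        res = fit_ivim(SignalCurve(palette_b, y))
        assert maps.f[0, 0, 0] == res.params.f
        assert maps.D[0, 0, 0] == res.params.D

    def test_outside_mask_zero_filled_and_shape_checked(self, palette_b):
        image = np.ones((2, 2, 1, palette_b.size))
        mask = np.zeros((2, 2, 1), bool)
        maps = fit_volume(image, palette_b, mask)
        assert not maps.S0.any()
        with pytest.raises(ValueError, match="mask shape"):
            fit_volume(image, palette_b, np.ones((3, 2, 1), bool))
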