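import numpy as np
import pytest

import ageadapt as aa
from ageadapt.exceptions import (
    DegenerateRegressionError,
    EmptyDataError,
    InsufficientDataError,
)
from ageadapt.fitting import _gd_basis
from conftest import make_dataset


def grid_search_constrained(data, design, n_sigma=600):
    """Brute-force (A, sigma) oracle: closed-form A on a dense sigma grid."""
    pre, y, cond = data.arrays()
    mu = np.array([design.adapt_age(c) for c in cond])
    best = np.inf
    for sigma in np.linspace(1.0, 100.0, n_sigma):
        g = _gd_basis(pre, mu, sigma)
        denom = g @ g
        amp = float(np.clip((y @ g) / denom, -20, 20)) if denom > 0 else 0.0
        best = min(best, float(np.sum((y - amp * g) ** 2)))
    return best


class TestFitConstrainedRepulsion:
    def test_exact_recovery_noiseless(self, noiseless_repulsion, design):
        fit = aa.fit_constrained_repulsion(noiseless_repulsion, design)
        assert fit.params.amplitude_A == pytest.approx(2.4, abs=1e-3)
        assert fit.params.sigma == pytest.approx(20.0, abs=1e-3)
        assert fit.sse == pytest.approx(0.0, abs=1e-6)
        assert fit.converged

    def test_all_zero_aftereffects_degenerate(self, design):
        pre = np.linspace(18, 89, 12)
        pts = []
        for c in ("young", "middle", "old"):
            for i, x in enumerate(pre):
                pts.append(aa.AftereffectPoint(c, f"{c}{i}", x, x))
        fit = aa.fit_constrained_repulsion(aa.RatingDataset(pts), design)
        assert fit.params.amplitude_A == pytest.approx(0.0, abs=1e-9)
        assert "unidentifiable" in fit.message

    def test_fitted_null_exactly_zero_at_adapt_ages(self, noisy_normalization, design):
        fit = aa.fit_constrained_repulsion(noisy_normalization, design)
        for c in ("young", "middle", "old"):
            pred = aa.predict_condition(design, c, fit.params, [design.adapt_age(c)])
            assert pred[0] == 0.0

    def test_matches_grid_search_oracle(self, design):
        rng = np.random.default_rng(202)
        for _ in range(5):
            pts = []
            for i in range(30):
                c = ("young", "middle", "old")[rng.integers(0, 3)]
                x = rng.uniform(18, 89)
                pts.append(aa.AftereffectPoint(c, f"f{i}", x, x + rng.normal(0, 3)))
            ds = aa.RatingDataset(pts)
            fit = aa.fit_constrained_repulsion(ds, design)
            oracle = grid_search_constrained(ds, design)
            assert fit.sse <= oracle * (1 + 1e-3)

    def test_empty_and_insufficient_data(self, design):
        with pytest.raises(EmptyDataError):
            aa.fit_constrained_repulsion(aa.RatingDataset([]), design)
        ds = make_dataset([20, 40, 60, 80], [1, -1, 1, -1], condition="young")
        with pytest.raises(InsufficientDataError):
            aa.fit_constrained_repulsion(ds, design)


class TestFitNormalization:
    def test_exact_recovery_noiseless(self, noiseless_normalization, design):
        fit = aa.fit_normalization(noiseless_normalization, design)
        assert fit.params.gain_k == pytest.approx(0.1, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_matches_grid_search(self, noisy_normalization, design):
        fit = aa.fit_normalization(noisy_normalization, design)
        _, y, cond = noisy_normalization.arrays()
        d = np.array([design.norm_age - design.adapt_age(c) for c in cond])
        grid = np.linspace(-1, 1, 200_001)
        sse = ((y[None, :] - grid[:, None] * d[None, :]) ** 2).sum(axis=1)
        assert fit.params.gain_k == pytest.approx(grid[np.argmin(sse)], abs=1e-5)
        assert fit.sse <= sse.min() + 1e-9

    def test_constant_condition_shifts_give_exact_gain(self, design):
        # young all +2.2, old all -0.8, middle all 0 -> k = 0.1 closed form
        pts = []
        for c, shift in (("young", 2.2), ("middle", 0.0), ("old", -0.8)):
            for i, x in enumerate(np.linspace(18, 89, 10)):
                pts.append(aa.AftereffectPoint(c, f"{c}{i}", x, x + shift))
        fit = aa.fit_normalization(aa.RatingDataset(pts), design)
        assert fit.params.gain_k == pytest.approx(0.1, abs=1e-12)

    def test_all_zero_gives_zero_gain(self, design):
        pts = [
            aa.AftereffectPoint(c, f"{c}{i}", x, x)
            for c in ("young", "old")
            for i, x in enumerate(np.linspace(18, 89, 6))
        ]
        fit = aa.fit_normalization(aa.RatingDataset(pts), design)
        assert fit.params.gain_k == 0.0

    def test_empty_rejected(self, design):
        with pytest.raises(EmptyDataError):
            aa.fit_normalization(aa.RatingDataset([]), design)


class TestFitUnconstrainedGD:
    def test_exact_recovery_noiseless(self):
        true = aa.GDRepulsionParams(amplitude_A=2.0, sigma=15.0, mu=57.0)
        pre = np.linspace(18, 89, 24)
        ds = make_dataset(pre, aa.gd_aftereffect(pre, true), condition="middle")
        fit = aa.fit_unconstrained_gd(ds, "middle")
        assert fit.params.amplitude_A == pytest.approx(2.0, abs=1e-4)
        assert fit.params.sigma == pytest.approx(15.0, abs=1e-3)
        assert fit.params.mu == pytest.approx(57.0, abs=1e-3)

    def test_broad_gd_approximates_linear_ramp(self):
        # a pure linear ramp through the range is matched by a very broad GD
        # whose near-null region is locally linear; residuals nearly match
        # the OLS line's
        pre = np.linspace(18, 89, 24)
        after = 0.05 * (pre - 53.5)
        ds = make_dataset(pre, after, condition="young")
        fit = aa.fit_unconstrained_gd(ds, "young")
        assert fit.params.sigma > 60.0
        _, _, resid = aa.fit_linear_regression(pre, after)
        rms_line = float(np.sqrt(np.mean(resid**2)))
        assert fit.rms <= rms_line + 0.05 * np.std(after)

    def test_offset_ramp_pushes_null_out_of_range(self):
        # an everywhere-positive ramp forces the fitted zero-crossing
        # outside the measured age range (an implausible "null" age)
        pre = np.linspace(18, 89, 24)
        ds = make_dataset(pre, 0.05 * pre + 1.0, condition="young")
        fit = aa.fit_unconstrained_gd(ds, "young")
        assert not 18.0 <= fit.params.mu <= 89.0

    def test_nested_within_constrained(self, design, noisy_normalization):
        # per-condition 3-parameter fits can only improve on the jointly
        # constrained 2-parameter fit, condition by condition
        con = aa.fit_constrained_repulsion(noisy_normalization, design)
        for c in noisy_normalization.conditions():
            pre, after, _ = noisy_normalization.subset(c).arrays()
            pred = aa.predict_condition(design, c, con.params, pre)
            sse_con = float(np.sum((after - pred) ** 2))
            unc = aa.fit_unconstrained_gd(noisy_normalization, c)
            assert unc.sse <= sse_con + 1e-6

    def test_too_few_points_rejected(self):
        ds = make_dataset([20, 40, 60], [1, 0, -1], condition="old")
        with pytest.raises(InsufficientDataError):
            aa.fit_unconstrained_gd(ds, "old")


class TestNestingInvariants:
    def test_fitted_models_beat_or_match_no_model(self, noisy_normalization, design):
        _, after, _ = noisy_normalization.arrays()
        sse_none = float(after @ after)
        assert aa.fit_normalization(noisy_normalization, design).sse <= sse_none + 1e-9
        assert (
            aa.fit_constrained_repulsion(noisy_normalization, design).sse
            <= sse_none + 1e-9
        )

    def test_recovery_error_shrinks_with_sample_size(self, design):
        # RMSE of the recovered amplitude decreases with faces per condition
        rmse = {}
        for n in (12, 24, 48):
            errs = []
            for i in range(40):
                cfg = aa.SimulationConfig(
                    design=design,
                    truth_model="repulsion",
                    truth_params=aa.GDRepulsionParams(2.4, 20.0),
                    n_faces_per_condition=n,
                    seed=1000 + i,
                )
                fit = aa.fit_constrained_repulsion(aa.generate_dataset(cfg), design)
                errs.append((fit.params.amplitude_A - 2.4) ** 2)
            rmse[n] = float(np.sqrt(np.mean(errs)))
        assert rmse[12] > rmse[48]


class TestFitLinearRegression:
    def test_constant_y_gives_intercept(self):
        x = np.arange(18, 90, dtype=float)
        slope, intercept, resid = aa.fit_linear_regression(x, np.full(x.size, 2.4))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(2.4, abs=1e-12)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_two_point_line(self):
        slope, intercept, _ = aa.fit_linear_regression([18.0, 89.0], [0.0, 7.1])
        assert slope == pytest.approx(0.1, abs=1e-12)
        assert intercept == pytest.approx(-1.8, abs=1e-12)

    def test_all_zero(self):
        slope, intercept, _ = aa.fit_linear_regression([18, 50, 89], [0, 0, 0])
        assert slope == 0.0 and intercept == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateRegressionError):
            aa.fit_linear_regression([50.0, 50.0, 50.0], [1.0, 2.0, 3.0])
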