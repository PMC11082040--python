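"""Circle-fit DBH extraction, power-model fitting, and prediction-bound filtering."""

import numpy as np
import pytest

from uasforest.data import NormalizedPointCloud, ParameterError, ValidationError
from uasforest.dbh import (
    extract_dbh,
    filter_pairs_by_bounds,
    fit_circle_ls,
    fit_power_model,
    impute_missing_dbh,
    make_synthetic_regional_model,
    prediction_interval,
)
from uasforest.detection import DetectedTree

from conftest import make_random_plot


def circle_points(cx, cy, r, n=8, rng=None, radial_sd=0.0):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rad = r + (rng.normal(0, radial_sd, n) if rng is not None and radial_sd else 0.0)
    return np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)])


class TestCircleFit:
    def test_exact_circle(self):
        fit = fit_circle_ls(circle_points(2.0, 3.0, 0.15))
        assert fit.center_x_m == pytest.approx(2.0, abs=1e-10)
        assert fit.center_y_m == pytest.approx(3.0, abs=1e-10)
        assert fit.radius_m == pytest.approx(0.15, abs=1e-10)
        assert fit.rms_m == pytest.approx(0.0, abs=1e-10)

    def test_translation_equivariance(self):
        pts = circle_points(2.0, 3.0, 0.15)
        a = fit_circle_ls(pts)
        b = fit_circle_ls(pts + 100.0)
        assert b.radius_m == pytest.approx(a.radius_m, abs=1e-9)
        assert b.center_x_m == pytest.approx(a.center_x_m + 100.0, abs=1e-9)

    def test_noisy_radius_nearly_unbiased(self):
        rng = np.random.default_rng(10)
        radii = [
            fit_circle_ls(circle_points(0, 0, 0.15, n=20, rng=rng, radial_sd=0.005)).radius_m
            for _ in range(500)
        ]
        assert abs(np.mean(radii) - 0.15) < 0.002

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(ValidationError):
            fit_circle_ls(pts)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_circle_ls([[0, 0], [1, 1]])


class TestExtractDbh:
    def make_slice(self, cx=5.0, cy=5.0, dbh_cm=30.0, n=24, extra=None):
        pts2d = circle_points(cx, cy, dbh_cm / 200.0, n=n)
        z = np.linspace(1.33, 1.41, n)
        pts = np.column_stack([pts2d, z])
        if extra is not None:
            pts = np.vstack([pts, extra])
        return NormalizedPointCloud(pts)

    def test_noiseless_stem_exact(self):
        fit = extract_dbh(self.make_slice(), DetectedTree(5.0, 5.0, 10.0))
        assert fit is not None
        assert fit.dbh_cm == pytest.approx(30.0, abs=0.1)

    def test_no_points_in_range_absent(self):
        assert extract_dbh(self.make_slice(), DetectedTree(50.0, 50.0, 10.0)) is None

    def test_too_few_points_absent(self):
        assert (
            extract_dbh(self.make_slice(n=6), DetectedTree(5.0, 5.0, 10.0), min_points=10)
            is None
        )

    def test_pure_clutter_rejected_by_quality_cap(self):
        """Branch-like uniform clutter should rarely pass the rms/radius gate."""
        rejected = 0
        n_seeds = 200
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            pts = np.column_stack(
                [
                    rng.uniform(4.0, 6.0, 30),
                    rng.uniform(4.0, 6.0, 30),
                    rng.uniform(1.32, 1.42, 30),
                ]
            )
            if extract_dbh(NormalizedPointCloud(pts), DetectedTree(5.0, 5.0, 10.0)) is None:
                rejected += 1
        assert rejected >= 0.95 * n_seeds


class TestPowerModel:
    def test_noiseless_recovery(self):
        h = np.linspace(2, 25, 100)
        model = fit_power_model(h, 4.29 * h**0.68)
        assert model.beta1 == pytest.approx(4.29, rel=1e-8)
        assert model.beta2 == pytest.approx(0.68, rel=1e-8)
        assert model.resid_se_cm == pytest.approx(0.0, abs=1e-8)

    def test_linear_special_case(self):
        h = np.linspace(1, 20, 50)
        model = fit_power_model(h, 2.5 * h)
        assert model.beta2 == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_monte_carlo(self):
        """Mean fitted exponent over noisy refits stays within 0.02 of truth."""
        b2_hats = []
        for s in range(100):
            rng = np.random.default_rng(s)
            h = rng.uniform(2, 25, 500)
            d = 4.29 * h**0.68 + rng.normal(0, 1.2, 500)
            b2_hats.append(fit_power_model(h, d).beta2)
        assert abs(np.mean(b2_hats) - 0.68) < 0.02

    def test_positive_inputs_required(self):
        with pytest.raises(ParameterError):
            fit_power_model([1, 2, -3, 4, 5], [1, 2, 3, 4, 5])


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(42)
    h = rng.uniform(2, 25, 200)
    d = 4.29 * h**0.68 + rng.normal(0, 1.2, 200)
    return fit_power_model(h, d)


@pytest.fixture(scope="module")
def regional():
    return make_synthetic_regional_model(seed=1)


class TestPredictionInterval:
    def test_contains_fitted_value(self, model):
        for h in (2.0, 8.0, 20.0):
            lo, hi = prediction_interval(model, h)
            assert lo < model.predict(h) < hi

    def test_width_monotone_in_level(self, model):
        lo90, hi90 = prediction_interval(model, 10.0, level=0.90)
        lo95, hi95 = prediction_interval(model, 10.0, level=0.95)
        assert hi95 - lo95 > hi90 - lo90

    def test_delta_and_mc_agree(self, model):
        lo_d, hi_d = prediction_interval(model, 10.0, level=0.90)
        lo_m, hi_m = prediction_interval(
            model, 10.0, level=0.90, method="mc", n_draws=40000,
            rng=np.random.default_rng(0),
        )
        assert lo_m == pytest.approx(lo_d, abs=0.15)
        assert hi_m == pytest.approx(hi_d, abs=0.15)

    def test_coverage_calibration(self):
        """90% interval covers fresh observations ~90% of the time."""
        total = covered = 0
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            h = rng.uniform(2, 25, 200)
            d = 4.29 * h**0.68 + rng.normal(0, 1.2, 200)
            model = fit_power_model(h, d)
            h_new = rng.uniform(2, 25, 500)
            d_new = 4.29 * h_new**0.68 + rng.normal(0, 1.2, 500)
            for hv, dv in zip(h_new, d_new):
                lo, hi = prediction_interval(model, hv, level=0.90)
                covered += lo <= dv <= hi
                total += 1
        assert covered / total == pytest.approx(0.90, abs=0.02)


class TestFilterAndImpute:
    def test_on_curve_pair_retained(self, regional):
        h = 10.0
        pairs = [(h, float(regional.predict(h)))]
        assert filter_pairs_by_bounds(pairs, regional) == pairs

    def test_gross_outlier_rejected(self, regional):
        h = 10.0
        pairs = [(h, 10.0 * float(regional.predict(h)))]
        assert filter_pairs_by_bounds(pairs, regional) == []

    def test_empty_input(self, regional):
        assert filter_pairs_by_bounds([], regional) == []

    def test_noiseless_pairs_all_retained_noisy_near_level(self, regional):
        rng = np.random.default_rng(3)
        h = rng.uniform(2, 25, 2000)
        on_curve = list(zip(h, regional.predict(h)))
        assert len(filter_pairs_by_bounds(on_curve, regional)) == len(on_curve)
        noisy = list(zip(h, regional.predict(h) + rng.normal(0, regional.resid_se_cm, len(h))))
        frac = len(filter_pairs_by_bounds(noisy, regional)) / len(noisy)
        assert frac == pytest.approx(0.90, abs=0.03)

    def test_impute_fills_only_missing_and_is_idempotent(self, regional):
        plot = make_random_plot(2, n=20, with_dbh=False)
        # give half the trees an "extracted" DBH
        import dataclasses

        trees = [
            dataclasses.replace(t, dbh_cm=20.0, dbh_origin="extracted")
            if i % 2 == 0
            else t
            for i, t in enumerate(plot.trees)
        ]
        plot = plot.with_trees(trees)
        out = impute_missing_dbh(plot, regional)
        for i, t in enumerate(out.trees):
            if i % 2 == 0:
                assert t.dbh_cm == 20.0 and t.dbh_origin == "extracted"
            else:
                assert t.dbh_cm == pytest.approx(float(regional.predict(t.height_m)))
                assert t.dbh_origin == "predicted"
        again = impute_missing_dbh(out, regional)
        assert again.trees == out.trees

    def test_impute_value_matches_power_law(self):
        from uasforest.dbh import PowerModel

        model = PowerModel(beta1=4.29, beta2=0.68, resid_se_cm=1.0, n=100,
                           param_cov=np.zeros((2, 2)))
        plot = make_random_plot(5, n=3, with_dbh=False)
        out = impute_missing_dbh(plot, model)
        t = out.trees[0]
        assert t.dbh_cm == pytest.approx(4.29 * t.height_m**0.68, rel=1e-12)
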