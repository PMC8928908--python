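import numpy as np
import pandas as pd
import pytest

from spatocc import (
    CovariateTable,
    DetectionMatrix,
    ModelSpec,
    OccupancyModel,
    ValidationError,
    count_parameters,
    fit_model,
)
from spatocc.likelihood import invlogit
from spatocc.model import _numeric_gradient, _numeric_hessian
from spatocc.simulate import SimulationConfig, simulate_dataset


class TestCountParameters:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            # global psi (6 covariates) + p with 3 covariates, correlated, pi free
            (ModelSpec(tuple("abcdef"), ("a", "b", "c")), 14),
            # univariate psi + 3-covariate p, correlated, pi free
            (ModelSpec(("a",), ("a", "b", "c")), 9),
            (ModelSpec(correlated=False), 2),
            (ModelSpec(pi_mode="stationary"), 4),
            (ModelSpec(pi_mode="fixed", pi_value=0.5), 4),
        ],
    )
    def test_counts(self, spec, expected):
        assert count_parameters(spec) == expected


class TestFitting:
    def test_standard_model_matches_grid_search(self):
        # 2-parameter intercept-only standard model vs. a 0.001-grid oracle
        rng = np.random.default_rng(6)
        occ = rng.random(120) < 0.6
        y = ((rng.random((120, 5)) < 0.4) & occ[:, None]).astype(np.int8)
        dm = DetectionMatrix([f"s{i}" for i in range(120)], y)
        fit = fit_model(dm, None, ModelSpec(correlated=False), n_starts=3, seed=0)
        grid = np.arange(0.001, 1.0, 0.001)
        from spatocc.likelihood import site_loglikelihoods

        best = (np.inf, None, None)
        for psi in grid[::10]:
            ll = np.array(
                [
                    site_loglikelihoods(y, np.full(120, psi), np.full((120, 5), p)).sum()
                    for p in grid[::10]
                ]
            )
            j = ll.argmax()
            if -ll[j] < best[0]:
                best = (-ll[j], psi, grid[::10][j])
        est = {e.name: e.value for e in fit.real_estimates()}
        assert est["psi"] == pytest.approx(best[1], abs=0.01)
        assert est["p"] == pytest.approx(best[2], abs=0.01)

    def test_parameter_recovery_standard_large_n(self):
        cfg = SimulationConfig(
            n_sites=2000,
            n_segments=20,
            theta0=1.0,
            theta1=1.0,
            pi=1.0,
            seed=21,
        )
        ds = simulate_dataset(cfg)
        fit = fit_model(ds.y, None, ModelSpec(correlated=False), n_starts=2, seed=0)
        est = {e.name: e for e in fit.real_estimates()}
        # Monte-Carlo SE of psi-hat is ~ sqrt(0.7*0.3/2000) ~ 0.010
        assert est["psi"].value == pytest.approx(0.7, abs=0.031)
        assert est["p"].value == pytest.approx(0.25, abs=0.02)

    def test_no_detections_pushes_psi_to_boundary(self):
        dm = DetectionMatrix([f"s{i}" for i in range(30)], np.zeros((30, 5), dtype=np.int8))
        fit = fit_model(dm, None, ModelSpec(correlated=False), n_starts=2, seed=0)
        assert fit.boundary_flags

    def test_refit_reproduces_loglik(self, medium_dataset):
        f1 = fit_model(medium_dataset.y, None, ModelSpec(), n_starts=2, seed=5)
        f2 = fit_model(medium_dataset.y, None, ModelSpec(), n_starts=2, seed=5)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_aic_identity(self, medium_fit):
        assert medium_fit.aic == pytest.approx(-2 * medium_fit.loglik + 2 * medium_fit.K, abs=1e-9)

    def test_site_permutation_invariance(self, medium_dataset):
        dm = medium_dataset.y
        rng = np.random.default_rng(1)
        perm = rng.permutation(dm.n_sites)
        dm_perm = DetectionMatrix([dm.site_ids[i] for i in perm], dm.y[perm])
        f1 = fit_model(dm, None, ModelSpec(), n_starts=1, seed=0)
        f2 = fit_model(dm_perm, None, ModelSpec(), n_starts=1, seed=0)
        np.testing.assert_allclose(f1.x, f2.x, atol=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-7)

    def test_gradient_small_and_hessian_pd_at_mle(self, medium_dataset, medium_fit):
        m = OccupancyModel(medium_dataset.y, None, ModelSpec())
        g = _numeric_gradient(m.nll, medium_fit.x)
        assert np.linalg.norm(g) < 1e-6
        H = _numeric_hessian(m.nll, medium_fit.x)
        assert (np.linalg.eigvalsh(H) > 0).all()

    def test_unscaled_covariates_rejected(self, tiny_matrix):
        covs = CovariateTable(["a", "b", "c"], pd.DataFrame({"x": [0.1, 0.5, 0.9]}))
        with pytest.raises(ValidationError, match="scaled"):
            OccupancyModel(tiny_matrix, covs, ModelSpec(psi_covariates=("x",)))

    def test_segment_level_detection_covariates(self):
        cfg = SimulationConfig(
            n_sites=300,
            n_segments=10,
            alpha_p=(-1.0, 1.2),
            p_covariates=("Term",),
            p_level="segment",
            covariate_generators={"Term": ("segment", 0.4)},
            seed=3,
        )
        ds = simulate_dataset(cfg)
        seg = {"Term": np.where(ds.records.indicators["Term"] < 0, 0,
                                ds.records.indicators["Term"]).astype(float)}
        model = OccupancyModel(ds.y, None, cfg.spec(), segment_covariates=seg)
        fit = model.fit(n_starts=2, seed=0)
        # the segment-indicator effect on detection should be recovered as positive
        alpha_term = fit.x[list(fit.coef_table().index).index("p:Term")]
        assert alpha_term > 0.3


class TestRealEstimates:
    def _manual_results(self, var):
        # intercept-only standard fit with a crafted vcov
        dm = DetectionMatrix(["a", "b"], np.array([[1, 0], [0, 0]], dtype=np.int8))
        fit = fit_model(dm, None, ModelSpec(correlated=False), n_starts=1, seed=0, polish=False)
        fit.x = np.array([0.0, 0.0])
        fit.vcov = np.diag([var, var])
        fit.converged = True
        return fit

    def test_logistic_derivative_at_zero(self):
        fit = self._manual_results(0.04)
        est = {e.name: e for e in fit.real_estimates()}
        assert est["p"].value == pytest.approx(0.5)
        assert est["p"].se == pytest.approx(0.25 * 0.2, abs=1e-12)

    def test_zero_variance_gives_zero_se(self):
        fit = self._manual_results(0.0)
        est = {e.name: e for e in fit.real_estimates()}
        assert est["psi"].se == 0.0

    def test_delta_method_matches_monte_carlo(self, medium_fit):
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(medium_fit.x, medium_fit.vcov, size=100_000)
        est = {e.name: e for e in medium_fit.real_estimates()}
        sl = medium_fit._block("p")
        mc_se = invlogit(draws[:, sl.start]).std()
        assert est["p"].se == pytest.approx(mc_se, rel=0.05)

    def test_ci_ordering_and_truncation(self, medium_fit):
        for e in medium_fit.real_estimates():
            assert 0 <= e.lci <= e.value <= e.uci <= 1


@pytest.fixture(scope="module")
def covariate_fit():
    cfg = SimulationConfig(
        n_sites=400,
        n_segments=15,
        beta_psi=(0.5, 1.0),
        psi_covariates=("EVI",),
        covariate_generators={"EVI": ("continuous",)},
        seed=12,
    )
    ds = simulate_dataset(cfg)
    fit = fit_model(ds.y, ds.covs, cfg.spec(), n_starts=2, seed=0)
    return ds, fit


class TestPredictPsi:
    def test_intercept_only_prediction_is_constant(self, medium_fit):
        ests = medium_fit.predict_psi()
        vals = {round(e.value, 12) for e in ests}
        assert len(vals) == 1

    def test_prediction_at_mean_matches_default_reals(self, covariate_fit):
        ds, fit = covariate_fit
        at_mean = fit.real_estimates()[0]
        # a pseudo-site at the covariate mean (scaled zero)
        covs0 = CovariateTable(
            ["mean"], pd.DataFrame({"EVI": [0.0]}), scaled=True, scale_params={"EVI": (0, 1)}
        )
        pred = fit.predict_psi(covs0)[0]
        assert pred.value == pytest.approx(at_mean.value, abs=1e-12)
        assert pred.se == pytest.approx(at_mean.se, abs=1e-12)

    def test_prediction_order_follows_linear_predictor(self, covariate_fit):
        ds, fit = covariate_fit
        ests = fit.predict_psi()
        x = ds.covs.values["EVI"].to_numpy()
        vals = np.array([e.value for e in ests])
        beta1 = fit.x[1]
        order = np.argsort(x if beta1 > 0 else -x)
        assert np.all(np.diff(vals[order]) >= -1e-12)

    def test_summary_renders(self, medium_fit):
        s = medium_fit.summary()
        assert "AIC" in s and "psi" in s
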