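import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatocc import (
    DetectionMatrix,
    ModelSpec,
    ParameterVector,
    ValidationError,
    build_linear_predictors,
    site_likelihood_bruteforce,
    site_likelihood_correlated,
    site_likelihood_standard,
    total_neg_log_likelihood,
)
from spatocc.likelihood import invlogit, logit, site_loglikelihoods

# hypothesis strategy: a random history with missing entries plus parameters
params_and_history = st.integers(1, 12).flatmap(
    lambda K: st.tuples(
        st.lists(st.sampled_from([-1, 0, 1]), min_size=K, max_size=K),
        st.lists(st.floats(0.01, 0.99), min_size=K, max_size=K),
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
    )
)


class TestStandardKernel:
    @pytest.mark.parametrize(
        "history, psi, p, expected",
        [
            ([1], 0.5, 0.5, 0.25),
            ([0], 0.5, 0.5, 0.75),
            ([0, 1, 0], 0.7, 0.3, 0.7 * 0.7 * 0.3 * 0.7),
        ],
    )
    def test_hand_computed(self, history, psi, p, expected):
        val = site_likelihood_standard(history, psi, np.full(len(history), p))
        assert val == pytest.approx(expected, abs=1e-12)

    def test_probability_validation(self):
        with pytest.raises(ValidationError):
            site_likelihood_standard([1], 1.5, [0.5])


class TestCorrelatedKernel:
    def test_single_segment(self):
        val = site_likelihood_correlated([1], 0.69, 0.3, 0.7, 0.5, [0.25])
        assert val == pytest.approx(0.69 * 0.5 * 0.25, abs=1e-12)

    def test_two_segment_path_enumeration(self):
        # paths (0,0)+(0,1)+(1,0)+(1,1) = 0.48+0.048+0.032+0.0512 = 0.6112
        val = site_likelihood_correlated([0, 0], 0.5, 0.2, 0.8, 0.4, [0.6, 0.6])
        assert val == pytest.approx(0.5 * 0.6112 + 0.5, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(params_and_history)
    def test_forward_equals_bruteforce(self, draw):
        h, p, psi, th0, th1, pi = draw
        a = site_likelihood_correlated(h, psi, th0, th1, pi, p)
        b = site_likelihood_bruteforce(h, psi, th0, th1, pi, p)
        assert a == pytest.approx(b, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params_and_history)
    def test_compiled_kernel_matches_reference(self, draw):
        h, p, psi, th0, th1, pi = draw
        y = np.array([h], dtype=np.int8)
        ll = site_loglikelihoods(y, np.array([psi]), np.array([p]), th0, th1, pi)
        ref = site_likelihood_correlated(h, psi, th0, th1, pi, p)
        assert np.exp(ll[0]) == pytest.approx(ref, abs=1e-12)

    def test_all_missing_history_is_uninformative(self):
        assert site_likelihood_correlated([-1, -1, -1], 0.3, 0.2, 0.8, 0.5, [0.4] * 3) == 1.0
        assert site_likelihood_bruteforce([-1, -1], 0.9, 0.1, 0.9, 0.2, [0.7, 0.7]) == 1.0

    def test_detection_with_zero_p_gives_zero(self):
        assert site_likelihood_correlated([1], 0.5, 0.3, 0.7, 0.5, [0.0]) == 0.0

    @pytest.mark.parametrize("K", [1, 4, 10])
    def test_history_probabilities_normalise(self, K):
        rng = np.random.default_rng(K)
        psi, th0, th1, pi = rng.uniform(0.05, 0.95, 4)
        p = rng.uniform(0.05, 0.95, K)
        hists = ((np.arange(2**K)[:, None] >> np.arange(K)[None, :]) & 1).astype(np.int8)
        total = sum(site_likelihood_correlated(h, psi, th0, th1, pi, p) for h in hists)
        assert total == pytest.approx(1.0, abs=1e-9)
        total_std = sum(site_likelihood_standard(h, psi, p) for h in hists)
        assert total_std == pytest.approx(1.0, abs=1e-9)

    def test_collapse_to_standard_when_chain_saturated(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            K = rng.integers(1, 10)
            h = rng.choice([0, 1], size=K)
            psi = rng.uniform(0.1, 0.9)
            p = rng.uniform(0.1, 0.9, K)
            a = site_likelihood_correlated(h, psi, 1.0, 1.0, 1.0, p)
            b = site_likelihood_standard(h, psi, p)
            assert a == pytest.approx(b, abs=1e-12)

    def test_collapse_to_thinned_standard_under_iid_availability(self):
        # theta0 = theta1 = pi = theta makes availability i.i.d., so detection
        # given occupancy is Bernoulli(theta * p)
        rng = np.random.default_rng(4)
        for _ in range(20):
            K = rng.integers(1, 10)
            h = rng.choice([0, 1], size=K)
            psi, theta, p = rng.uniform(0.1, 0.9, 3)
            a = site_likelihood_correlated(h, psi, theta, theta, theta, np.full(K, p))
            b = site_likelihood_standard(h, psi, np.full(K, theta * p))
            assert a == pytest.approx(b, abs=1e-12)

    def test_no_detection_probability_bounded_below_by_absence(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            K = rng.integers(1, 12)
            psi, th0, th1, pi = rng.uniform(0.01, 0.99, 4)
            p = rng.uniform(0.01, 0.99, K)
            val = site_likelihood_correlated(np.zeros(K, int), psi, th0, th1, pi, p)
            assert val >= 1 - psi - 1e-12

    def test_monotone_in_psi_given_a_detection(self):
        rng = np.random.default_rng(10)
        h = np.array([0, 1, 0, 0, 1])
        p = rng.uniform(0.1, 0.9, 5)
        vals = [
            site_likelihood_correlated(h, psi, 0.3, 0.7, 0.45, p)
            for psi in np.linspace(0.05, 0.95, 10)
        ]
        assert np.all(np.diff(vals) >= -1e-15)

    def test_bruteforce_guard(self):
        with pytest.raises(ValidationError):
            site_likelihood_bruteforce(np.zeros(17, int), 0.5, 0.5, 0.5, 0.5, np.full(17, 0.5))


class TestLinearPredictors:
    def test_intercept_zero_gives_half(self):
        spec = ModelSpec(correlated=False)
        pv = ParameterVector(np.array([0.0]), np.array([0.0]))
        psi, p, *_ = build_linear_predictors(spec, pv, None, n_segments=3, n_sites=4)
        np.testing.assert_allclose(psi, 0.5)
        np.testing.assert_allclose(p, 0.5)

    def test_logistic_closed_form(self):
        import pandas as pd

        from spatocc import CovariateTable

        covs = CovariateTable(
            ["a"], pd.DataFrame({"x": [1.0]}), scaled=True, scale_params={"x": (0, 1)}
        )
        spec = ModelSpec(psi_covariates=("x",), correlated=False)
        pv = ParameterVector(np.array([0.0, 1.0]), np.array([0.0]))
        psi, *_ = build_linear_predictors(spec, pv, covs, n_segments=1)
        assert psi[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_stationary_pi_is_chain_equilibrium(self):
        spec = ModelSpec(pi_mode="stationary")
        pv = ParameterVector(
            np.array([0.0]), np.array([0.0]), logit(0.2), logit(0.8), None
        )
        *_, pi = build_linear_predictors(spec, pv, None, n_segments=1, n_sites=1)
        assert pi == pytest.approx(0.2 / (1 + 0.2 - 0.8), abs=1e-12)

    def test_unknown_covariate_errors(self):
        import pandas as pd

        from spatocc import CovariateTable

        covs = CovariateTable(["a"], pd.DataFrame({"x": [1.0]}), scaled=True)
        spec = ModelSpec(psi_covariates=("nope",))
        pv = ParameterVector(np.zeros(2), np.zeros(1), 0.0, 0.0, 0.0)
        with pytest.raises(ValidationError, match="nope"):
            build_linear_predictors(spec, pv, covs, n_segments=1)


class TestPacking:
    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec(correlated=False),
            ModelSpec(),
            ModelSpec(("a", "b"), ("c",), pi_mode="stationary"),
            ModelSpec(("a",), (), pi_mode="fixed", pi_value=0.4),
        ],
    )
    def test_pack_unpack_roundtrip(self, spec):
        rng = np.random.default_rng(0)
        from spatocc.model import count_parameters

        x = rng.normal(size=count_parameters(spec))
        pv = ParameterVector.unpack(x, spec)
        np.testing.assert_array_equal(pv.pack(), x)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValidationError):
            ParameterVector.unpack(np.zeros(3), ModelSpec())


class TestTotalNLL:
    def test_single_site_closed_form(self):
        dm = DetectionMatrix(["a"], np.array([[1]], dtype=np.int8))
        spec = ModelSpec(correlated=False)
        nll = total_neg_log_likelihood(np.zeros(2), dm, None, spec)
        assert nll == pytest.approx(-np.log(0.25), abs=1e-9)

    def test_additive_over_concatenated_datasets(self):
        rng = np.random.default_rng(2)
        y1 = rng.choice([0, 1], size=(5, 6)).astype(np.int8)
        y2 = rng.choice([0, 1], size=(7, 6)).astype(np.int8)
        spec = ModelSpec()
        x = rng.normal(size=5)
        n1 = total_neg_log_likelihood(x, y1, None, spec)
        n2 = total_neg_log_likelihood(x, y2, None, spec)
        n12 = total_neg_log_likelihood(x, np.vstack([y1, y2]), None, spec)
        assert n12 == pytest.approx(n1 + n2, abs=1e-9)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(7)
        y = rng.choice([-1, 0, 1], size=(8, 6), p=[0.1, 0.6, 0.3]).astype(np.int8)
        spec = ModelSpec()
        x = rng.normal(scale=0.5, size=5)
        pv = ParameterVector.unpack(x, spec)
        psi = invlogit(pv.beta_psi[0])
        p = invlogit(pv.alpha_p[0])
        th0, th1, pi = (
            invlogit(pv.logit_theta0),
            invlogit(pv.logit_theta1),
            invlogit(pv.logit_pi),
        )
        expected = -sum(
            np.log(site_likelihood_bruteforce(row, psi, th0, th1, pi, np.full(6, p)))
            for row in y
        )
        got = total_neg_log_likelihood(x, y, None, spec)
        assert got == pytest.approx(expected, abs=1e-10)
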