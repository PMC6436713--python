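"""Proportional-odds likelihood core: probabilities, log-likelihood, deviance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import ordcar as oc
from ordcar.likelihood import (
    CutpointSet,
    ParameterState,
    category_probabilities,
    deviance,
    linear_predictor,
    log_likelihood,
)

from conftest import random_dataset, random_state


def brute_force_loglik(dataset, state, structure):
    """Independent per-row oracle: enumerate each patient's full category
    probability vector from the two logistic CDFs and pick the realised one."""
    kappa = state.cutpoints.kappa
    total = 0.0
    for i in range(dataset.n):
        eta = float(np.dot(dataset.X[i], state.beta))
        if state.f is not None:
            eta += state.f[dataset.facility_index[i] - 1]
        if structure in ("unstructured", "convolution"):
            eta += state.u[dataset.county_index[i] - 1]
        if structure in ("structured", "convolution"):
            eta += state.phi[dataset.county_index[i] - 1]
        cdf = [0.0] + [1.0 / (1.0 + np.exp(-(k - eta))) for k in kappa] + [1.0]
        probs = [cdf[k + 1] - cdf[k] for k in range(len(cdf) - 1)]
        total += np.log(probs[dataset.y[i] - 1])
    return total


class TestCutpoints:
    def test_ordering_enforced_by_construction(self):
        cp = CutpointSet(g1=-0.5, increments=[1.5])
        assert np.allclose(cp.kappa, [-0.5, 1.0])
        with pytest.raises(ValueError):
            CutpointSet(g1=0.0, increments=[-1.0])
        with pytest.raises(ValueError):
            CutpointSet.from_kappa([1.0, 0.5])


class TestLinearPredictor:
    def test_convolution_arithmetic(self):
        state = ParameterState(
            beta=[0.5, -1.0], cutpoints=CutpointSet(0.0, [1.0]),
            u=[0.1], f=[-0.1], phi=[0.0],
        )
        eta = linear_predictor([1.0, 0.0], state, facility=1, county=1,
                               structure="convolution")
        assert eta == pytest.approx(0.5)

    def test_all_zero_state(self):
        state = ParameterState(
            beta=[0.0, 0.0], cutpoints=CutpointSet(0.0, [1.0]),
            u=[0.0], f=[0.0], phi=[0.0],
        )
        assert linear_predictor([3.0, -2.0], state, 1, 1, "convolution") == 0.0

    def test_structured_equals_convolution_when_u_zero(self):
        rng = np.random.default_rng(0)
        state = random_state(rng)
        state.u = np.zeros_like(state.u)
        x = rng.standard_normal(2)
        a = linear_predictor(x, state, 2, 3, "structured")
        b = linear_predictor(x, state, 2, 3, "convolution")
        assert a == pytest.approx(b)

    def test_index_out_of_range(self):
        state = ParameterState(beta=[0.0], cutpoints=CutpointSet(0.0, [1.0]),
                               u=[0.0], f=[0.0], phi=[0.0])
        with pytest.raises(IndexError):
            linear_predictor([1.0], state, facility=5, county=1, structure="convolution")


class TestCategoryProbabilities:
    def test_closed_form_at_zero(self):
        cp = CutpointSet.from_kappa([0.0, np.log(3)])
        assert np.allclose(category_probabilities(0.0, cp), [0.5, 0.25, 0.25])

    def test_large_eta_concentrates_on_top_category(self):
        cp = CutpointSet.from_kappa([0.0, 1.0])
        p = category_probabilities(50.0, cp)
        assert p[2] == pytest.approx(1.0, abs=1e-12)
        assert p[0] < 1e-15 and p[1] < 1e-15

    def test_unit_eta_against_direct_cdf_difference(self):
        cp = CutpointSet.from_kappa([0.0, 1.0])
        p = category_probabilities(1.0, cp)
        # independent evaluation of the two logistic CDFs
        c1, c2 = expit(0.0 - 1.0), expit(1.0 - 1.0)
        assert p[0] == pytest.approx(c1, abs=1e-14)
        assert p[1] == pytest.approx(c2 - c1, abs=1e-14)
        assert p[2] == pytest.approx(1 - c2, abs=1e-14)
        assert p[0] == pytest.approx(1 / (1 + np.e))
        assert p[2] == pytest.approx(0.5)

    @given(
        eta=st.floats(min_value=-30, max_value=30),
        g1=st.floats(min_value=-5, max_value=5),
        g2=st.floats(min_value=0.01, max_value=10),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_probabilities_normalised_and_monotone(self, eta, g1, g2):
        cp = CutpointSet(g1, [g2])
        p = category_probabilities(eta, cp)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.sum(p) == pytest.approx(1.0, abs=1e-12)
        # increasing eta moves mass upward: P(y > k) nondecreasing in eta
        p_hi = category_probabilities(eta + 0.5, cp)
        assert 1 - p_hi[0] >= 1 - p[0] - 1e-12
        assert p_hi[2] >= p[2] - 1e-12


class TestLogLikelihood:
    def test_single_patient_half_probability(self):
        ds = random_dataset(np.random.default_rng(0), n=1, p=1)
        ds.y[:] = 1
        ds.X[:] = 0.0
        ds.X[0, 0] = 1.0  # avoid the constant-column guard via direct set
        state = ParameterState(beta=[0.0], cutpoints=CutpointSet.from_kappa([0.0, 5.0]),
                               u=np.zeros(3), f=np.zeros(4), phi=np.zeros(3))
        ll = log_likelihood(ds, state, "convolution")
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)
        assert deviance(ds, state, "convolution") == pytest.approx(1.386294, abs=1e-6)

    def test_additivity_over_duplicated_rows(self):
        rng = np.random.default_rng(1)
        ds = random_dataset(rng, n=1, p=2)
        state = random_state(rng)
        single = log_likelihood(ds, state, "convolution")
        ds2 = random_dataset(rng, n=1, p=2)
        ds2.y = np.concatenate([ds.y, ds.y])
        ds2.X = np.vstack([ds.X, ds.X])
        ds2.facility_index = np.concatenate([ds.facility_index, ds.facility_index])
        ds2.county_index = np.concatenate([ds.county_index, ds.county_index])
        assert log_likelihood(ds2, state, "convolution") == pytest.approx(2 * single, abs=1e-12)

    @pytest.mark.parametrize("structure", ["unstructured", "structured", "convolution"])
    def test_matches_brute_force_oracle(self, structure):
        rng = np.random.default_rng(7)
        for _ in range(25):
            ds = random_dataset(rng, n=20)
            state = random_state(rng)
            ours = log_likelihood(ds, state, structure)
            oracle = brute_force_loglik(ds, state, structure)
            assert ours == pytest.approx(oracle, abs=1e-10)
            assert deviance(ds, state, structure) == pytest.approx(-2 * oracle, abs=1e-9)

    def test_perfect_prediction_deviance_tends_to_zero(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n=10)
        ds.y[:] = 3
        state = random_state(rng)
        state.beta = np.zeros(2)
        state.u = np.full(3, 30.0)  # eta -> +inf, y = K
        state.f = np.zeros(4)
        state.phi = np.zeros(3)
        assert deviance(ds, state, "unstructured") < 1e-8

    def test_location_invariance_of_cutpoints_and_eta(self):
        # shifting every cutpoint and eta by the same constant leaves the
        # likelihood unchanged (why the model carries no intercept)
        rng = np.random.default_rng(4)
        ds = random_dataset(rng, n=30)
        state = random_state(rng)
        base = log_likelihood(ds, state, "convolution")
        c = 1.7
        shifted = state.copy()
        shifted.cutpoints = CutpointSet.from_kappa(state.cutpoints.kappa + c)
        shifted.u = state.u + c  # adds c to eta for every patient
        assert log_likelihood(ds, shifted, "convolution") == pytest.approx(base, abs=1e-9)

    def test_never_minus_inf_for_finite_eta(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, n=5)
        ds.y[:] = 1
        state = random_state(rng)
        state.u = np.full(3, 200.0)  # probability of category 1 underflows
        ll = log_likelihood(ds, state, "unstructured")
        assert np.isfinite(ll)


class TestAgainstMaximumLikelihood:
    def test_flat_prior_mode_matches_independent_mle(self):
        """On covariate-only data the maximiser of this module's likelihood
        must agree with an independently implemented ordinal MLE
        (statsmodels OrderedModel) — a dual-route check of the likelihood."""
        from scipy.optimize import minimize
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        cfg = oc.SimulationConfig(
            n_counties=4, n_facilities=8, n_patients=4000,
            covariates=[
                oc.CovariateSpec("x1", "continuous", "patient", "b", beta=0.8),
                oc.CovariateSpec("x2", "continuous", "patient", "b", beta=-0.5),
            ],
            structure="none", facility_effects=False,
            adjacency_kind="lattice", seed=12,
        )
        truth = oc.TruthRecord(beta_true=np.array([0.8, -0.5]),
                               cutpoints_true=np.array([-0.5, 1.0]))
        ds, _ = oc.generate_dataset(cfg, truth)

        def negll(theta):
            state = ParameterState(
                beta=theta[:2],
                cutpoints=CutpointSet(theta[2], [np.exp(theta[3])]),
                f=np.zeros(8),
            )
            return -log_likelihood(ds, state, "none")

        opt = minimize(negll, x0=np.zeros(4), method="BFGS")
        ours = opt.x[:2]

        sm_fit = OrderedModel(ds.y, ds.X, distr="logit").fit(method="bfgs", disp=False)
        theirs = sm_fit.params[:2]
        assert np.allclose(ours, theirs, atol=1e-3)
        assert np.allclose(ours, truth.beta_true, atol=0.1)
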