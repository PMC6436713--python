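"""Sampler mechanics: determinism, invariants, DIC, summaries, diagnostics."""

import warnings

import numpy as np
import pytest

import ordcar as oc
from ordcar.sampler import McmcConfig, ModelSpec, PosteriorDraws, run_mcmc
from ordcar.summaries import diagnostics, dic_from_deviance, summarize


class TestDeterminism:
    def test_identical_seed_gives_bit_identical_draws(self, small_study):
        dataset, adjacency, _ = small_study
        spec = ModelSpec(structure="convolution")
        cfg = McmcConfig(n_draws=50, burnin=50, seed=123)
        d1 = run_mcmc(dataset, adjacency, spec, cfg)
        d2 = run_mcmc(dataset, adjacency, spec, cfg)
        for name in d1.samples:
            assert np.array_equal(d1.samples[name], d2.samples[name])

    def test_different_seed_differs(self, small_study):
        dataset, adjacency, _ = small_study
        spec = ModelSpec(structure="unstructured")
        a = run_mcmc(dataset, None, spec, McmcConfig(n_draws=30, burnin=30, seed=1))
        b = run_mcmc(dataset, None, spec, McmcConfig(n_draws=30, burnin=30, seed=2))
        assert not np.array_equal(a.samples["beta"], b.samples["beta"])


class TestChainInvariants:
    def test_cutpoints_ordered_and_increment_positive_every_draw(self, small_fit):
        kappa = small_fit.draws.stacked("kappa")
        assert np.all(np.diff(kappa, axis=1) > 0)
        g = small_fit.draws.stacked("g")
        assert np.all(g[:, 1] > 0)

    def test_phi_centred_every_draw(self, small_fit):
        phi = small_fit.draws.stacked("phi")
        assert np.max(np.abs(phi.mean(axis=1))) < 1e-12

    def test_precisions_positive_every_draw(self, small_fit):
        for name in ("tau_h", "tau_v", "tau_c"):
            assert np.all(small_fit.draws.stacked(name) > 0)

    def test_retained_draw_count(self, small_fit):
        assert small_fit.draws.n_draws == 400

    def test_acceptance_rates_in_unit_interval(self, small_fit):
        for rates in small_fit.draws.acceptance.values():
            assert all(0.0 <= r <= 1.0 for r in rates.values())


class TestArgumentChecks:
    def test_spatial_structure_requires_adjacency(self, small_study):
        dataset, _, _ = small_study
        with pytest.raises(ValueError, match="adjacency"):
            run_mcmc(dataset, None, ModelSpec(structure="convolution"),
                     McmcConfig(n_draws=5, burnin=0))

    def test_zero_variation_covariate_rejected_with_name(self, small_study):
        dataset, adjacency, _ = small_study
        bad = dataset.to_frame()
        ds2 = oc.OrdinalDataset.from_frame(bad, blocks=dataset.blocks,
                                           n_facilities=dataset.n_facilities,
                                           n_counties=dataset.n_counties)
        ds2.X = ds2.X.copy()
        ds2.X[:, 0] = 1.0  # degenerate after construction
        with pytest.raises(ValueError, match=ds2.columns[0]):
            run_mcmc(ds2, adjacency, ModelSpec(structure="unstructured"),
                     McmcConfig(n_draws=5, burnin=0))


class TestToyPosteriorMoments:
    def test_two_parameter_normal_target(self):
        """Detailed-balance smoke test: with likelihood suppressed the two
        beta blocks target their independent normal priors; MH marginal
        moments must match the analytic values within MC error."""
        ds = oc.OrdinalDataset(
            y=np.zeros(0, dtype=int), X=np.zeros((0, 2)), columns=["a", "b"],
            blocks={"a": "b", "b": "b"}, facility_index=np.zeros(0, dtype=int),
            county_index=np.zeros(0, dtype=int), n_facilities=2, n_counties=2,
        )
        spec = ModelSpec(structure="none", facility_effects=False)
        draws = run_mcmc(ds, None, spec, McmcConfig(n_draws=20000, burnin=2000, seed=5))
        beta = draws.stacked("beta")
        sd = np.sqrt(1 / 1e-3)
        ess_floor = 500  # conservative for an adapted RW chain
        for j in range(2):
            assert abs(beta[:, j].mean()) < 4 * sd / np.sqrt(ess_floor)
            assert beta[:, j].std() == pytest.approx(sd, rel=0.15)


class TestDic:
    def test_toy_hand_arithmetic(self):
        # deviance draws {0, 4} (theta in {0, 2}, D = theta^2), plug-in at
        # the mean theta = 1 gives D = 1
        res = dic_from_deviance([0.0, 4.0], 1.0)
        assert res.d_bar == 2.0
        assert res.p_d == 1.0
        assert res.dic == 3.0

    def test_components_identity_on_real_fit(self, small_fit, small_study):
        dic = small_fit.dic
        assert dic.p_d == pytest.approx(dic.d_bar - dic.d_at_mean, abs=1e-12)
        assert dic.dic == pytest.approx(dic.d_bar + dic.p_d, abs=1e-12)
        assert dic.d_bar > 0

    def test_informative_covariates_beat_null_model(self):
        cfg = oc.study_config(seed=21, n_counties=8, n_facilities=24, n_patients=900)
        dataset, adjacency, _ = oc.simulate_study(cfg)
        mcmc = McmcConfig(n_draws=600, burnin=600, seed=3)
        full = oc.SpatialOrdinalModel(dataset, adjacency, structure="unstructured").fit(mcmc)
        null = oc.SpatialOrdinalModel(
            dataset.subset_columns(["anc_skilled"]),  # near-null single covariate
            adjacency, structure="unstructured").fit(mcmc)
        assert full.dic.dic < null.dic.dic

    def test_pure_noise_covariates_raise_pd(self):
        # several noise columns so the pD increase (~1 per extra parameter)
        # clears the Monte-Carlo noise of the deviance summaries
        rng = np.random.default_rng(8)
        cfg = oc.study_config(seed=22, n_counties=8, n_facilities=24, n_patients=900)
        dataset, adjacency, _ = oc.simulate_study(cfg)
        df = dataset.to_frame()
        blocks = dict(dataset.blocks)
        for k in range(6):
            df.insert(len(df.columns) - 3, f"noise{k}", rng.standard_normal(dataset.n))
            blocks[f"noise{k}"] = "b"
        ds2 = oc.OrdinalDataset.from_frame(df, blocks=blocks,
                                           n_facilities=dataset.n_facilities,
                                           n_counties=dataset.n_counties)
        mcmc = McmcConfig(n_draws=1500, burnin=800, seed=4)
        base = oc.SpatialOrdinalModel(dataset, adjacency, structure="unstructured").fit(mcmc)
        noisy = oc.SpatialOrdinalModel(ds2, adjacency, structure="unstructured").fit(mcmc)
        assert noisy.dic.p_d > base.dic.p_d
        assert abs(noisy.dic.dic - base.dic.dic) < 30


class TestSummarize:
    def test_or_draws_exp_arithmetic(self):
        draws = _fake_draws(beta=np.array([[0.0], [0.2], [0.4]]))
        summ = summarize(draws, parameters=["beta"]).table
        row = summ.iloc[0]
        ors = np.exp([0.0, 0.2, 0.4])
        assert row["or_mean"] == pytest.approx(ors.mean())
        assert row["or_median"] == pytest.approx(1.2214, abs=1e-4)

    def test_symmetric_draws_interval_straddles_one(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 0.5, size=(4000, 1))
        summ = summarize(_fake_draws(beta=b), parameters=["beta"]).table.iloc[0]
        assert summ["or_2.5%"] < 1 < summ["or_97.5%"]

    def test_interval_endpoints_match_sorting_oracle(self):
        rng = np.random.default_rng(1)
        b = rng.normal(0.3, 0.2, size=(5000, 1))
        summ = summarize(_fake_draws(beta=b), parameters=["beta"]).table.iloc[0]
        sorted_or = np.sort(np.exp(b[:, 0]))
        lo = np.quantile(sorted_or, 0.025)
        hi = np.quantile(sorted_or, 0.975)
        assert summ["or_2.5%"] == pytest.approx(lo)
        assert summ["or_97.5%"] == pytest.approx(hi)

    def test_unknown_parameter_group(self):
        with pytest.raises(KeyError):
            summarize(_fake_draws(beta=np.zeros((10, 1))), parameters=["bogus"])


def _fake_draws(beta):
    beta = np.asarray(beta, dtype=float)
    samples = {
        "beta": beta[None, :, :],
        "kappa": np.tile([0.0, 1.0], (1, beta.shape[0], 1)),
        "tau_h": np.ones((1, beta.shape[0], 1)),
        "tau_v": np.ones((1, beta.shape[0], 1)),
        "tau_c": np.ones((1, beta.shape[0], 1)),
        "deviance": np.ones((1, beta.shape[0], 1)),
    }
    return PosteriorDraws(
        samples=samples,
        param_names={"beta": [f"b{j}" for j in range(beta.shape[1])],
                     "kappa": ["kappa1", "kappa2"]},
        structure="unstructured",
        acceptance={},
        config=McmcConfig(n_draws=beta.shape[0], burnin=0),
    )


class TestDiagnostics:
    def test_iid_pseudo_draws_give_rhat_near_one(self):
        rng = np.random.default_rng(2)
        draws = _fake_draws(beta=rng.standard_normal((2000, 1)))
        draws.samples["beta"] = rng.standard_normal((4, 500, 1))
        rep = diagnostics(draws, groups=("beta",))
        rhat = rep["parameters"]["b0"]["rhat"]
        assert abs(rhat - 1.0) < 0.05
        assert rep["parameters"]["b0"]["converged"]

    def test_disjoint_chains_flagged(self):
        draws = _fake_draws(beta=np.zeros((100, 1)))
        chains = np.stack([np.random.default_rng(3).normal(0, 0.1, (500, 1)),
                           np.random.default_rng(4).normal(10, 0.1, (500, 1))])
        draws.samples["beta"] = chains
        rep = diagnostics(draws, groups=("beta",))
        # rank-normalised split R-hat saturates near sqrt(2) for two chains
        # with disjoint supports; anything this far above 1 must be flagged
        assert rep["parameters"]["b0"]["rhat"] > 1.2
        assert not rep["parameters"]["b0"]["converged"]

    def test_single_chain_warns_and_omits_rhat(self, small_fit):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            rep = small_fit.diagnostics(groups=("beta",))
        assert any("single chain" in str(w.message) for w in caught)
        assert "rhat" not in next(iter(rep["parameters"].values()))

    def test_thinning_lowers_lag1_autocorrelation(self, small_study):
        dataset, adjacency, _ = small_study
        spec = ModelSpec(structure="unstructured")
        thin1 = run_mcmc(dataset, None, spec, McmcConfig(n_draws=400, burnin=300, thinning=1, seed=9))
        thin5 = run_mcmc(dataset, None, spec, McmcConfig(n_draws=80, burnin=300, thinning=5, seed=9))
        def lag1(d):
            x = d.stacked("beta")[:, 0]
            x = x - x.mean()
            return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))
        assert lag1(thin5) < lag1(thin1)


class TestPersistence:
    def test_save_load_round_trip(self, small_fit, tmp_path):
        out = tmp_path / "draws"
        small_fit.save(out)
        back = PosteriorDraws.load(out)
        for name in small_fit.draws.samples:
            assert np.allclose(back.samples[name], small_fit.draws.samples[name])
        assert back.structure == "convolution"
        assert back.fingerprint == small_fit.draws.fingerprint
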