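import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trafficsem as ts
from trafficsem.config import ConfigurationError
from trafficsem.sem import GibbsSampler, SEMSpec, build_sem


def _short_mcmc(**kw):
    defaults = dict(chains=2, iterations=1500, burn_in=500, seed=123)
    defaults.update(kw)
    return ts.MCMCSettings(**defaults)


class TestSpecValidation:
    def test_unknown_outcome(self):
        with pytest.raises(ConfigurationError):
            SEMSpec(outcome="nope")

    def test_reference_must_be_listed(self):
        with pytest.raises(ConfigurationError):
            SEMSpec(reference_pollutant="o3")
        with pytest.raises(ConfigurationError):
            SEMSpec(reference_marker="lf")

    def test_collapse_needs_single_indicator(self):
        with pytest.raises(ConfigurationError):
            SEMSpec(collapse_single_indicator=True)

    def test_iterations_exceed_burnin(self):
        with pytest.raises(ConfigurationError):
            ts.MCMCSettings(iterations=100, burn_in=100)


class TestBuildSem:
    def test_counts_match_study_layout(self):
        cfg = ts.CohortConfig(n_participants=700, seed=0, exact_visit_counts=True)
        ds = ts.simulate_cohort(cfg)
        model = build_sem(ds.model_design(), ds.visits, SEMSpec())
        assert model.n == 1467
        assert model.n_participants == 700

    def test_single_participant_single_visit_flags_random_intercept(self, small_dataset):
        visits = small_dataset.visits.iloc[:1]
        design = small_dataset.model_design().iloc[:1]
        with pytest.warns(UserWarning, match="unidentifiable"):
            model = build_sem(design, visits, SEMSpec())
        assert model.info["random_intercept_unidentifiable"]
        assert model.n == 1

    def test_modifier_adds_interaction_construct(self, small_dataset, small_design):
        model = build_sem(small_dataset.visits, small_dataset.visits, SEMSpec())
        assert "traffic_x_mod" not in model.gamma_names()
        model = build_sem(
            small_design, small_dataset.visits, SEMSpec(modifier="diabetic")
        )
        assert "traffic_x_mod" in model.gamma_names()

    def test_missing_modifier_column_rejected(self, small_dataset, small_design):
        visits = small_dataset.visits.drop(columns=["diabetic"])
        with pytest.raises(ValueError, match="modifier"):
            build_sem(small_design, visits, SEMSpec(modifier="diabetic"))

    def test_no_shared_visits_rejected(self, small_dataset, small_design):
        visits = small_dataset.visits.copy()
        visits["visit_id"] = visits["visit_id"] + 10_000
        with pytest.raises(ValueError):
            build_sem(small_design, visits, SEMSpec())

    def test_incomplete_visits_dropped_and_counted(self, small_dataset, small_design):
        visits = small_dataset.visits.copy()
        visits.loc[visits.index[:7], "log_hf"] = np.nan
        model = build_sem(small_design, visits, SEMSpec())
        assert model.info["n_dropped_incomplete"] == 7
        assert model.n == len(visits) - 7


class TestGibbsMechanics:
    def test_fixed_seed_identical_chain(self, small_dataset, small_design):
        spec = SEMSpec(mcmc=_short_mcmc(chains=1, iterations=60, burn_in=20))
        a = ts.fit_sem(small_design, small_dataset.visits, spec, compute_diagnostics=False)
        b = ts.fit_sem(small_design, small_dataset.visits, spec, compute_diagnostics=False)
        for name in a.names():
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_constraints_hold_in_every_draw(self, small_dataset, small_design):
        spec = SEMSpec(outcome="joint", mcmc=_short_mcmc(chains=1, iterations=120, burn_in=40))
        res = ts.fit_sem(small_design, small_dataset.visits, spec, compute_diagnostics=False)
        # reference loadings are fixed, hence never sampled
        assert "lambda1[bc]" not in res.draws
        assert "alpha1[hf]" not in res.draws
        # no free latent intercepts exist in the parameterisation
        assert not any("phi0" in n or "gamma[const]" in n for n in res.names())
        for name in res.names():
            if name.startswith("tau"):
                assert (res.get(name) > 0).all()

    def test_degenerate_zero_measurement_error_limit(self, small_dataset, small_design):
        model = build_sem(small_design, small_dataset.visits, SEMSpec())
        s = GibbsSampler(model, np.random.default_rng(0))
        truth = small_dataset.truth
        s.lam0 = np.array([truth.lambda0[p] for p in model.pollutant_names])
        s.lam1 = np.array([truth.lambda1[p] for p in model.pollutant_names])
        s.tau_x = np.full(4, 1e14)
        s.tau_T = 1.0
        s.phi = np.zeros(4)
        s.gamma = np.zeros(len(model.gamma_names()))
        s.update_traffic()
        # conditional collapses onto the indicator-implied weighted value
        w = s.lam1**2 * s.tau_x
        implied = ((model.X - s.lam0) @ (s.lam1 * s.tau_x)) / w.sum()
        np.testing.assert_allclose(s.T, implied, atol=1e-4)

    def test_gamma_conditional_matches_conjugate_oracle(self, small_dataset):
        """Toy model: gamma drawn repeatedly matches the closed-form posterior
        of a Bayesian regression of the latent tone on traffic."""
        visits = small_dataset.visits.iloc[:40]
        design = small_dataset.model_design().iloc[:40]
        spec = SEMSpec(covariates=(), include_seasonal=False)
        model = build_sem(design, visits, spec)
        rng = np.random.default_rng(99)
        s = GibbsSampler(model, rng)
        s.T = model.X[:, 0] - model.X[:, 0].mean()
        s.P = model.Y[:, 0] - model.Y[:, 0].mean()
        s.a = np.zeros(model.n_participants)
        s.tau_P = 2.0
        draws = np.empty(5000)
        for i in range(5000):
            s.update_gamma()
            draws[i] = s.gamma[0]
        v0 = 1.0 / spec.priors.coef_variance
        A = float(s.tau_P * (s.T @ s.T) + v0)
        mean = float(s.tau_P * (s.T @ s.P)) / A
        sd = float(np.sqrt(1.0 / A))
        assert stats.kstest(draws, "norm", args=(mean, sd)).pvalue > 0.01
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(5000)


class TestReferenceScaling:
    def test_flipping_reference_marker_rescales_gamma(self):
        """With SDNN as reference the latent tone is alpha1_sdnn times the
        HF-scale tone, so gamma rescales by the HF-model SDNN loading."""
        truth = ts.GenerativeTruth(gamma_traffic=-1.0)
        cfg = ts.CohortConfig(
            n_participants=400,
            study_start="2003-01-01",
            study_end="2005-12-31",
            seed=21,
            truth=truth,
        )
        ds = ts.simulate_cohort(cfg)
        design = ds.model_design()
        mc = _short_mcmc(chains=2, iterations=2000, burn_in=800, seed=55)
        res_hf = ts.fit_sem(
            design, ds.visits, SEMSpec(reference_marker="hf", mcmc=mc),
            compute_diagnostics=False,
        )
        res_sdnn = ts.fit_sem(
            design, ds.visits, SEMSpec(reference_marker="sdnn", mcmc=mc),
            compute_diagnostics=False,
        )
        g_hf = res_hf.get("gamma[traffic]").mean()
        a_sdnn = res_hf.get("alpha1[sdnn]").mean()
        g_sdnn = res_sdnn.get("gamma[traffic]").mean()
        sd = res_sdnn.get("gamma[traffic]").std()
        assert g_sdnn == pytest.approx(a_sdnn * g_hf, abs=0.5 * sd)


class TestEffectModification:
    def test_requires_modifier(self, small_dataset, small_design):
        with pytest.raises(ConfigurationError):
            ts.fit_effect_modification(small_design, small_dataset.visits, SEMSpec())

    def test_constant_modifier_rejected(self, small_dataset, small_design):
        visits = small_dataset.visits.copy()
        visits["diabetic"] = 0
        with pytest.raises(ValueError, match="constant"):
            ts.fit_effect_modification(
                small_design, visits, SEMSpec(modifier="diabetic")
            )

    def test_non_dichotomous_modifier_rejected(self, small_dataset, small_design):
        visits = small_dataset.visits.copy()
        visits["diabetic"] = visits["glucose"]
        with pytest.raises(ValueError, match="0/1"):
            ts.fit_effect_modification(
                small_design, visits, SEMSpec(modifier="diabetic")
            )

    def test_group_specific_slopes_attached(self, small_dataset, small_design):
        spec = SEMSpec(
            modifier="diabetic",
            mcmc=_short_mcmc(chains=1, iterations=200, burn_in=80),
        )
        res = ts.fit_effect_modification(small_design, small_dataset.visits, spec)
        assert "gamma[traffic|mod=1]" in res.draws
        np.testing.assert_allclose(
            res.draws["gamma[traffic|mod=1]"],
            res.draws["gamma[traffic]"] + res.draws["gamma[traffic_x_mod]"],
        )

    def test_tiny_subgroup_warns(self, small_dataset, small_design):
        visits = small_dataset.visits.copy()
        visits["rare"] = 0
        visits.loc[visits.index[0], "rare"] = 1
        spec = SEMSpec(
            modifier="rare", mcmc=_short_mcmc(chains=1, iterations=150, burn_in=50)
        )
        with pytest.warns(UserWarning, match="subgroup"):
            ts.fit_effect_modification(small_design, visits, spec)


class TestNullEffect:
    def test_null_generator_gives_symmetric_sign_probability(self):
        """gamma1 = 0 in the generator: Pr(gamma1 < 0) near 0.5 on average."""
        probs = []
        for rep in range(4):
            truth = ts.GenerativeTruth(gamma_traffic=0.0)
            cfg = ts.CohortConfig(
                n_participants=200,
                study_start="2004-01-01",
                study_end="2005-12-31",
                seed=300 + rep,
                truth=truth,
            )
            ds = ts.simulate_cohort(cfg)
            res = ts.fit_sem(
                ds.model_design(),
                ds.visits,
                SEMSpec(mcmc=_short_mcmc(chains=1, iterations=1200, burn_in=400, seed=rep)),
                compute_diagnostics=False,
            )
            probs.append(np.mean(res.get("gamma[traffic]") < 0))
        assert 0.15 < np.mean(probs) < 0.85
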