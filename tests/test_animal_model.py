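import numpy as np
import pandas as pd
import pytest
from scipy import stats

from halfsibqg import (
    AnimalModelSpec,
    MCMCConfig,
    PhenotypeTable,
    PosteriorSample,
    autocorrelation,
    autocorrelation_check,
    build_prior,
    dic,
    gibbs_fit,
    heritability,
    log10_transform,
    simulate_design,
    solve_prior_scale,
)
from halfsibqg.animal_model import ModelError
from conftest import single_pop_config


def env0_log(cfg):
    ped, tab, truth = simulate_design(cfg)
    sub = tab.df[tab.df["ethanol"] == "0"].reset_index(drop=True)
    return ped, log10_transform(PhenotypeTable(df=sub, scale="raw"))


def residual_only_spec(trait="ldt"):
    return AnimalModelSpec(traits=(trait,), include_additive=False,
                           include_dam=False, include_line=False)


class TestPrior:
    def test_equal_partition_rule(self, small_log):
        _, ped, tl, _ = small_log
        spec = AnimalModelSpec.for_trait("ldt")
        prior = build_prior(tl, spec, MCMCConfig())
        T = tl.df["ldt"].var(ddof=1)
        for comp in ("A", "C", "R", "E"):
            assert prior.expectation(comp) == pytest.approx(T / 4)

    def test_single_observation_rejected(self):
        df = pd.DataFrame({c: ["x"] for c in ("id", "population", "line",
                                              "ethanol", "sex", "chamber", "hour")})
        for t in ("ldt", "pdt", "tdt", "mb", "rmr"):
            df[t] = [1.0]
        tab = PhenotypeTable(df=df, scale="log10")
        with pytest.raises(ModelError):
            build_prior(tab, AnimalModelSpec.for_trait("ldt"), MCMCConfig())

    def test_inverse_gamma_mean_relation(self):
        # for nu > 2 the scale is recoverable from the mean formula
        s = solve_prior_scale(0.01, nu=5.0)
        assert 5.0 * s / (5.0 - 2.0) == pytest.approx(0.01)
        # nu = 1 has no finite mean: scale is the centre itself
        assert solve_prior_scale(0.01, nu=1.0) == 0.01


class TestGibbsFit:
    def test_conjugate_closed_form_posterior(self):
        # residual-only model: the marginal posterior of E is scaled-inv-chi2
        rng = np.random.default_rng(0)
        n = 60
        y = rng.normal(1.5, 0.2, size=n)
        df = pd.DataFrame({
            "id": [f"i{k}" for k in range(n)],
            "population": "SF", "line": "L1", "ethanol": "0",
            "sex": "F", "chamber": "ch1", "hour": "h0",
            "ldt": y, "pdt": np.nan, "tdt": np.nan, "mb": np.nan, "rmr": np.nan,
        })
        tab = PhenotypeTable(df=df, scale="log10")
        from halfsibqg import Pedigree
        ped = Pedigree.from_entries([(f"i{k}", None, None) for k in range(n)])
        spec = AnimalModelSpec(traits=("ldt",), fixed=(), include_additive=False,
                               include_dam=False, include_line=False)
        cfg = MCMCConfig(n_iter=10_500, burn_in=500, thin=5, seed=4)
        ps = gibbs_fit(tab, ped, spec, cfg)
        draws = ps.components["E"]
        assert len(draws) == 2000
        prior = build_prior(tab, spec, cfg)
        nu0, s0 = prior.components["E"]
        S = np.sum((y - y.mean()) ** 2)
        a_post = (nu0 + n - 1) / 2
        scale_post = (nu0 * s0 + S) / 2
        ks = stats.kstest(draws, stats.invgamma(a_post, scale=scale_post).cdf)
        assert ks.statistic < 0.05

    def test_null_additive_variance_recovers_zero(self):
        cfg = single_pop_config(seed=8, n_sires=12, h2=[0.0] * 5, c_frac=0.1)
        ped, tl = env0_log(cfg)
        mc = MCMCConfig(n_iter=6000, burn_in=1000, thin=5, seed=1)
        ps = gibbs_fit(tl, ped, AnimalModelSpec.for_trait("ldt"), mc)
        est = heritability(ps)
        assert est.hpd_low < 0.05

    def test_chain_exactly_reproducible_and_seed_consistent(self):
        cfg = single_pop_config(seed=9, n_sires=8, h2=[0.3] * 5)
        ped, tl = env0_log(cfg)
        spec = AnimalModelSpec.for_trait("ldt")
        mc = MCMCConfig(n_iter=4000, burn_in=1000, thin=3, seed=7)
        a = gibbs_fit(tl, ped, spec, mc)
        b = gibbs_fit(tl, ped, spec, mc)
        for comp in a.components:
            assert np.array_equal(a.components[comp], b.components[comp])
        # a different seed agrees within Monte-Carlo error
        c = gibbs_fit(tl, ped, spec,
                      MCMCConfig(n_iter=12_000, burn_in=2000, thin=5, seed=8))
        d = gibbs_fit(tl, ped, spec,
                      MCMCConfig(n_iter=12_000, burn_in=2000, thin=5, seed=9))
        for comp in ("A", "E"):
            x, y_ = c.components[comp], d.components[comp]
            mcse = np.sqrt(x.var() / (len(x) / 10) + y_.var() / (len(y_) / 10))
            assert abs(x.mean() - y_.mean()) < 3 * mcse

    def test_diffuse_prior_matches_frequentist_residual_variance(self):
        rng = np.random.default_rng(3)
        n = 200
        y = rng.normal(0.0, 0.15, size=n)
        df = pd.DataFrame({
            "id": [f"i{k}" for k in range(n)],
            "population": "SF", "line": "L1", "ethanol": "0",
            "sex": "F", "chamber": "ch1", "hour": "h0",
            "ldt": y, "pdt": np.nan, "tdt": np.nan, "mb": np.nan, "rmr": np.nan,
        })
        tab = PhenotypeTable(df=df, scale="log10")
        from halfsibqg import Pedigree, Prior
        ped = Pedigree.from_entries([(f"i{k}", None, None) for k in range(n)])
        spec = AnimalModelSpec(traits=("ldt",), fixed=(), include_additive=False,
                               include_dam=False, include_line=False)
        prior = Prior(components={"E": (1e-3, 1e-6)}, n_traits=1,
                      phenotypic_variance=np.array([y.var(ddof=1)]))
        ps = gibbs_fit(tab, ped, spec,
                       MCMCConfig(n_iter=8000, burn_in=1000, thin=3, seed=2),
                       prior=prior)
        freq = np.sum((y - y.mean()) ** 2) / (n - 1)
        assert abs(ps.components["E"].mean() - freq) / freq < 0.05

    def test_bivariate_draws_positive_definite(self, small_log):
        _, ped, tl, _ = small_log
        sub = PhenotypeTable(
            df=tl.df[tl.df["ethanol"] == "0"].reset_index(drop=True),
            scale="log10",
        )
        mc = MCMCConfig(n_iter=1500, burn_in=500, thin=2, seed=3)
        ps = gibbs_fit(sub, ped, AnimalModelSpec.for_trait("ldt", "mb"), mc)
        for comp, arr in ps.components.items():
            np.linalg.cholesky(arr)     # raises if any draw is not PD


class TestAutocorrelation:
    def test_white_noise_below_threshold(self):
        x = np.random.default_rng(5).standard_normal(10_000)
        assert abs(autocorrelation(x, 1)) < 0.05

    def test_ar1_estimate_near_truth(self):
        rng = np.random.default_rng(6)
        rho = 0.9
        x = np.empty(20_000)
        x[0] = 0.0
        for k in range(1, len(x)):
            x[k] = rho * x[k - 1] + rng.standard_normal()
        assert abs(autocorrelation(x, 1) - rho) < 0.05

    def test_short_chain_rejected(self):
        with pytest.raises(ModelError, match="too short"):
            autocorrelation(np.array([1.0, 2.0]), 1)

    def test_constant_chain_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            out = autocorrelation(np.ones(50), 1)
        assert np.isnan(out)

    def test_check_flags_components(self, small_log):
        _, ped, tl, _ = small_log
        mc = MCMCConfig(n_iter=3000, burn_in=1000, thin=2, seed=11)
        ps = gibbs_fit(tl, ped, AnimalModelSpec.for_trait("mb"), mc)
        out = autocorrelation_check(ps)
        assert set(out["parameter"]) == {"A", "C", "R", "E"}
        assert out["autocorr"].notna().all()


class TestDic:
    def _degenerate_sample(self):
        return PosteriorSample(
            traits=("ldt",),
            components={"E": np.full(50, 0.3)},
            fixed=np.zeros((50, 1)),
            fixed_names=["intercept"],
            deviance=np.full(50, 123.4),
            d_at_mean=123.4,
            n_obs=10,
            spec=None, cfg=None,
        )

    def test_degenerate_chain_gives_zero_pd(self):
        DIC, pD, dbar = dic(self._degenerate_sample())
        assert pD == pytest.approx(0.0, abs=1e-10)
        assert DIC == pytest.approx(123.4, abs=1e-9)
        assert dbar == pytest.approx(123.4)

    def test_missing_deviance_trace_errors(self):
        ps = self._degenerate_sample()
        ps.deviance = None
        with pytest.raises(ModelError, match="deviance"):
            dic(ps)

    def test_pd_invariant_to_response_location(self):
        cfg = single_pop_config(seed=14, n_sires=6, h2=[0.3] * 5)
        ped, tl = env0_log(cfg)
        mc = MCMCConfig(n_iter=3000, burn_in=500, thin=2, seed=5)
        ps1 = gibbs_fit(tl, ped, AnimalModelSpec.for_trait("ldt"), mc)
        tl2 = PhenotypeTable(df=tl.df.assign(ldt=tl.df["ldt"] + 5.0),
                             scale="log10")
        ps2 = gibbs_fit(tl2, ped, AnimalModelSpec.for_trait("ldt"), mc)
        assert dic(ps1)[1] == pytest.approx(dic(ps2)[1], rel=1e-6)

    def test_dic_prefers_complete_model_under_strong_additive_signal(self):
        cfg = single_pop_config(seed=15, n_sires=20, h2=[0.6] * 5, c_frac=0.05)
        ped, tl = env0_log(cfg)
        mc = MCMCConfig(n_iter=8000, burn_in=2000, thin=5, seed=6)
        acre = gibbs_fit(tl, ped, AnimalModelSpec.for_trait("ldt"), mc)
        cre = gibbs_fit(tl, ped,
                        AnimalModelSpec.for_trait("ldt", include_additive=False),
                        MCMCConfig(n_iter=8000, burn_in=2000, thin=5, seed=7))
        assert dic(acre)[0] < dic(cre)[0]
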