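import numpy as np
import pandas as pd
import pytest

from divkit.glmm import (DiversityRichnessModel, _tail_prob,
                         compress_unit_interval, rhat, simulate_response,
                         spearman_effort_check)

from oracles import naive_spearman

FAST_MCMC = dict(n_chains=3, n_samples=6_000, burn_in=2_000, thin=5)


def _covariates(rng, n=20):
    S = rng.integers(5, 44, n).astype(float)
    days = rng.integers(3, 31, n).astype(float)
    alt = rng.uniform(0, 3670, n)
    return S, days, alt


def _fit(family, truth, seed, mcmc=FAST_MCMC):
    rng = np.random.default_rng(seed)
    S, days, alt = _covariates(rng)
    z = (alt - alt.mean()) / alt.std()
    y = simulate_response(family, truth, S, np.log(days), z, rng)
    model = DiversityRichnessModel(y, S, days, alt, family=family)
    return model.fit(seed=seed, **(mcmc or {}))


class TestModelValidation:
    def test_beta_family_rejects_values_above_one(self, rng):
        S, days, alt = _covariates(rng)
        y = rng.uniform(1.5, 3.0, 20)  # e.g. MPD values
        with pytest.raises(ValueError, match="beta family"):
            DiversityRichnessModel(y, S, days, alt, family="beta")

    def test_too_few_sites_rejected(self, rng):
        with pytest.raises(ValueError, match="8 sites"):
            DiversityRichnessModel([0.5] * 5, [5] * 5, [3] * 5, [0] * 5)

    def test_boundary_compression_keeps_open_interval(self):
        y = np.array([0.0, 0.5, 1.0, 0.2])
        c = compress_unit_interval(y)
        assert np.all((c > 0) & (c < 1))

    def test_from_dataframe(self, rng):
        S, days, alt = _covariates(rng)
        df = pd.DataFrame({"FDiv": rng.uniform(0.2, 0.8, 20), "S": S,
                           "sampling_days": days, "altitude_m": alt})
        m = DiversityRichnessModel.from_dataframe(df, "FDiv")
        assert m.family == "beta" and m.name == "FDiv"


class TestRhat:
    def test_identical_chains_near_one(self, rng):
        draws = rng.standard_normal(500)
        chains = np.vstack([draws, draws])
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self, rng):
        chains = np.vstack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert rhat(chains) > 1.5

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.standard_normal((1, 100)))

    def test_agrees_with_arviz_reference(self, rng):
        import arviz as az

        chains = rng.standard_normal((4, 400)) + rng.normal(
            0, 0.05, size=(4, 1))
        ours = rhat(chains)
        ref = float(az.rhat(az.convert_to_dataset(chains[None].transpose(1, 2, 0))
                            ).to_array().values.item())
        assert ours == pytest.approx(ref, abs=0.01)


class TestSpearman:
    def test_perfectly_monotone(self):
        rho, _ = spearman_effort_check([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman_effort_check([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_tied_example_matches_rank_formula(self):
        S = [5, 7, 7, 10, 12, 12]
        days = [3, 3, 8, 9, 9, 15]
        rho, _ = spearman_effort_check(S, days)
        assert rho == pytest.approx(naive_spearman(S, days), abs=1e-12)

    def test_constant_vector_undefined(self):
        rho, p = spearman_effort_check([3, 3, 3, 3, 3], [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)


class TestPosteriorPredictive:
    def test_identical_replicates_give_half(self):
        t = np.array([3.0, 5.0, 2.0])
        assert _tail_prob(t, t) == 0.5

    def test_well_specified_fit_passes(self):
        # fully converged chains: the fit ratio is tail-sensitive, so the
        # short-chain settings used elsewhere are not enough here
        res = _fit("beta", dict(beta0=-1.0, beta1=0.08, phi=30.0), seed=10,
                   mcmc=None)
        p, ratio = res.posterior_predictive_check()
        assert 0.025 < p < 0.975
        assert 0.5 < ratio < 2.0

    def test_fit_ratio_near_one_when_well_specified(self):
        res = _fit("normal", dict(beta0=1.0, beta1=0.05, sigma=0.2), seed=21,
                   mcmc=None)
        _, ratio = res.posterior_predictive_check()
        assert 0.5 < ratio < 2.0


class TestFit:
    def test_beta_recovery_and_convergence(self):
        truth = dict(beta0=-1.0, beta1=0.08, phi=30.0)
        res = _fit("beta", truth, seed=1)
        lo, hi = res.credible_interval("beta1")
        assert lo < truth["beta1"] < hi
        assert res.converged

    def test_normal_recovery(self):
        truth = dict(beta0=0.5, beta1=0.04, sigma=0.15)
        res = _fit("normal", truth, seed=2)
        lo, hi = res.credible_interval("beta1")
        assert lo < truth["beta1"] < hi

    def test_seeded_determinism(self):
        truth = dict(beta0=-0.5, beta1=0.05, phi=20.0)
        a = _fit("beta", truth, seed=3)
        b = _fit("beta", truth, seed=3)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_normal_posterior_close_to_ols_slope(self):
        # with no effort/altitude signal the beta1 posterior should sit on
        # the least-squares estimate
        rng = np.random.default_rng(4)
        S, days, alt = _covariates(rng)
        y = 0.3 + 0.05 * S + rng.normal(0, 0.1, 20)
        res = DiversityRichnessModel(y, S, days, alt, family="normal").fit(
            seed=4, **FAST_MCMC)
        slope = np.polyfit(S, y, 1)[0]
        sd = res.summary().set_index("parameter").loc["beta1", "sd"]
        assert res.posterior_mean("beta1") == pytest.approx(slope, abs=2.5 * sd)

    def test_summary_structure(self):
        res = _fit("beta", dict(beta0=-1.0, beta1=0.05, phi=25.0), seed=6)
        summ = res.summary()
        assert list(summ.columns) == ["parameter", "mean", "sd", "q2.5",
                                      "q97.5", "rhat"]
        assert set(summ["parameter"]) == set(res.param_names)
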