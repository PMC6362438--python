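"""MCMC fit: diagnostics, posterior predictive checks, summaries."""

import numpy as np
import pandas as pd
import pytest

import habitatipm as hp
from habitatipm.fit import (FAMILY_NAMES, PosteriorDraws, PriorSpec, fit_ipm,
                            posterior_predictive_check, rhat_diagnostic,
                            split_rhat, summarize_posterior)


class TestRhat:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        chains = np.stack([x, x, x])
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.05)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 400), rng.normal(5, 1, 400)])
        assert split_rhat(chains) > 1.1

    def test_single_chain_is_an_error(self, fixture_fit):
        one = PosteriorDraws(
            nat=fixture_fit.nat[:1], mu=fixture_fit.mu[:1],
            sigma=fixture_fit.sigma[:1], psi_lin=fixture_fit.psi_lin[:1],
            pc=fixture_fit.pc[:1], imm_mean=fixture_fit.imm_mean[:1],
            n0=fixture_fit.n0[:1], recruits=fixture_fit.recruits[:1],
            adult_flows=fixture_fit.adult_flows[:1],
            immigrants=fixture_fit.immigrants[:1],
            loglik=fixture_fit.loglik[:1], n_years=fixture_fit.n_years)
        with pytest.raises(ValueError):
            rhat_diagnostic(one)

    def test_matches_arviz_reference(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(size=(3, 400)), axis=1) * 0.05 \
            + rng.normal(size=(3, 400))
        ours = split_rhat(x)
        theirs = float(np.asarray(
            arviz.rhat(arviz.convert_to_dataset(x, group="posterior"),
                       method="split")["x"]).ravel()[0])
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_fit_mean_rates_converge(self, fixture_fit):
        rh = rhat_diagnostic(fixture_fit)
        means = rh[[f"mean_{n}" for n in FAMILY_NAMES
                    if n.startswith(("b_", "fled_"))]]
        assert (means < 1.1).all()


class TestFit:
    def test_draw_shapes_and_validity(self, fixture_fit, default_dataset):
        d = fixture_fit
        T = default_dataset.truth.config.years
        assert d.nat.shape == (2, 1200, 18, T)
        assert np.all(d.nat[:, :, :4] >= 0) and np.all(d.nat[:, :, :4] <= 1)
        assert np.all(d.nat[:, :, 4:8] > 0.0)
        assert np.all(d.n0 >= 0)
        assert np.all(d.immigrants >= 0)
        assert np.all((d.pc > 0) & (d.pc < 1))
        assert np.isfinite(d.loglik).all()
        nb = d.nb()
        assert np.all(nb.sum(axis=2) > 0)

    def test_posterior_centers_on_generating_rates(self, fixture_fit,
                                                   default_dataset):
        # one-seed sanity check on the best-identified parameter: breeding
        # success of Old breeders in Short habitat (largest sample sizes)
        tr = default_dataset.truth
        truth = np.mean([p.b[1, 0] for p in tr.params])
        post = fixture_fit.series("b_O_S").mean(axis=-1)
        assert abs(post.mean() - truth) < 0.05

    def test_no_breeding_data_recovers_prior(self, default_dataset):
        # with every monitored-site count zeroed, b is informed only by its
        # prior and the (weak) count/CMR pathways: the posterior of the
        # link-scale mean must stay far wider than in the data-rich fit
        obs = default_dataset.observed
        empty = obs.breeding.df.copy()
        empty["n_monitored"] = 0
        empty["n_successful"] = 0
        ds2 = hp.ObservedDataset(
            breeding=hp.BreedingTable(empty), fledgling=obs.fledgling,
            adults=obs.adults, juveniles=obs.juveniles, counts=obs.counts)
        d2 = fit_ipm(ds2, chains=2, iterations=400, burnin=300, seed=5)
        d1 = fit_ipm(obs, chains=2, iterations=400, burnin=300, seed=5)
        sd_without = d2.mu[:, :, 1].std()
        sd_with = d1.mu[:, :, 1].std()
        assert sd_without > 2 * sd_with

    def test_priorspec_serialization(self):
        pri = PriorSpec()
        arr = pri.as_array()
        assert arr[1] == 10.0 and arr[2] == -5.0 and arr[3] == 20.0
        assert arr[0] == pytest.approx(1 / np.sqrt(0.001))
        assert arr[4] == pytest.approx(1 / np.sqrt(0.01))


class TestPosteriorPredictive:
    def test_pvalues_moderate_on_model_data(self, fixture_fit,
                                            default_dataset):
        ppc = posterior_predictive_check(fixture_fit,
                                         default_dataset.observed,
                                         n_rep=60, seed=0)
        assert set(ppc.index) == {"breeding", "fledgling", "counts",
                                  "adult_cmr", "juvenile"}
        assert ((ppc > 0.0) & (ppc < 1.0)).all()
        # data were generated from the model: no submodel should misfit
        assert ((ppc > 0.02) & (ppc < 0.98)).all()

    def test_gross_count_misfit_detected(self, fixture_fit,
                                         default_dataset):
        obs = default_dataset.observed
        inflated = obs.counts.df.copy()
        inflated["count"] = inflated["count"] * 10
        ds2 = hp.ObservedDataset(
            breeding=obs.breeding, fledgling=obs.fledgling,
            adults=obs.adults, juveniles=obs.juveniles,
            counts=hp.CountTable(inflated))
        ppc = posterior_predictive_check(fixture_fit, ds2, n_rep=40, seed=1)
        assert ppc["counts"] < 0.02

    def test_stable_under_draw_subsampling(self, fixture_fit,
                                           default_dataset):
        p1 = posterior_predictive_check(fixture_fit,
                                        default_dataset.observed,
                                        n_rep=60, seed=2)
        p2 = posterior_predictive_check(fixture_fit,
                                        default_dataset.observed,
                                        n_rep=60, seed=3)
        assert np.all(np.abs(p1 - p2) < 0.35)


class TestSummaries:
    def _tiny_draws(self) -> PosteriorDraws:
        # hand-built 1-chain x 2-draw, 3-year draws object
        T = 3
        nat = np.zeros((1, 2, 18, T))
        nat[0, 0] = 0.5
        nat[0, 1, :, :] = np.linspace(0.2, 0.4, T)[None, :]
        shape = (1, 2)
        return PosteriorDraws(
            nat=nat, mu=np.zeros(shape + (18,)),
            sigma=np.zeros(shape + (18,)), psi_lin=np.zeros(shape + (6,)),
            pc=np.full(shape + (2,), 0.9),
            imm_mean=np.ones(shape + (4, T - 1)),
            n0=np.tile(np.array([5.0, 5.0, 13.0, 13.0]), shape + (1,)),
            recruits=np.full(shape + (2, 2, T - 1), 2.0),
            adult_flows=np.full(shape + (4, 2, T - 1), 3.0),
            immigrants=np.full(shape + (4, T - 1), 1.0),
            loglik=np.zeros(shape), n_years=T)

    def test_hand_computed_means_and_cvs(self):
        d = self._tiny_draws()
        summ = summarize_posterior(d)
        # draw 0 has constant rates 0.5 -> CV 0; draw 1 linspace 0.2..0.4
        row = summ.loc["b_Y_S"]
        lin = np.linspace(0.2, 0.4, 3)
        exp_mean = np.mean([0.5, lin.mean()])
        exp_cv = np.mean([0.0, lin.std() / lin.mean()])
        assert row["mean"] == pytest.approx(exp_mean, abs=1e-12)
        assert row["cv"] == pytest.approx(exp_cv, abs=1e-12)
        # both-sex fledgling row is twice the per-sex mean
        assert summ.loc["f_Y_S", "mean"] == pytest.approx(
            2 * summ.loc["fled_Y_S", "mean"], abs=1e-12)

    def test_constant_draws_have_zero_cv(self):
        d = self._tiny_draws()
        summ = summarize_posterior(d)
        # nb is constant over years in this object -> proportions CV 0
        assert summ.loc["n_O_S", "cv"] == pytest.approx(0.0, abs=1e-12)

    def test_fixture_summary_is_plausible(self, fixture_fit):
        summ = summarize_posterior(fixture_fit)
        assert 0.5 < summ.loc["b_O_S", "mean"] < 1.0
        assert summ.loc["omega_total", "mean"] > 0.1
        assert summ.loc["productivity_S", "mean"] > \
            summ.loc["productivity_T", "mean"]
        lam = summ.loc["lambda_geometric_mean"]
        assert 0.8 < lam["mean"] < 1.2
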