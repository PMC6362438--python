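"""Submodel likelihoods against closed forms and brute-force enumeration."""

import itertools

import numpy as np
import pytest
from scipy import stats

import habitatipm as hp
from habitatipm.likelihoods import (AdultHistories, BreedingTable,
                                    CountLatentState, CountTable,
                                    FledglingTable, JuvenileHistories,
                                    adult_multievent_loglik,
                                    breeding_success_loglik,
                                    build_adult_transition_matrix,
                                    build_observation_matrix,
                                    count_state_space_loglik,
                                    fledgling_loglik,
                                    juvenile_recruitment_loglik)

from conftest import random_annual_params


def random_params_list(seed: int, T: int):
    rng = np.random.default_rng(seed)
    return [random_annual_params(rng) for _ in range(T)]


class TestBreedingLoglik:
    def test_certain_success(self):
        tab = BreedingTable.from_records([(0, 0, 0, 1, 1)])
        b = np.ones((2, 2, 1))
        assert breeding_success_loglik(tab, b) == 0.0

    def test_closed_form_half(self):
        tab = BreedingTable.from_records([(0, 1, 1, 2, 1)])
        b = np.full((2, 2, 1), 0.5)
        assert breeding_success_loglik(tab, b) == pytest.approx(np.log(0.5))

    def test_matches_scipy_binomial_oracle(self):
        rng = np.random.default_rng(0)
        T = 24
        b = rng.uniform(0.05, 0.95, (2, 2, T))
        rows = []
        expected = 0.0
        for t in range(T):
            for a in range(2):
                for h in range(2):
                    R = int(rng.integers(0, 40))
                    B = int(rng.integers(0, R + 1)) if R else 0
                    rows.append((t, a, h, R, B))
                    if R:
                        expected += stats.binom.logpmf(B, R, b[a, h, t])
        got = breeding_success_loglik(BreedingTable.from_records(rows), b)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_more_successes_than_trials_rejected(self):
        with pytest.raises(ValueError):
            BreedingTable.from_records([(0, 0, 0, 2, 3)])


class TestFledglingLoglik:
    def test_boundary_rate_zero(self):
        tab = FledglingTable.from_records([(0, 0, 0, 10, 10)])
        fled = np.full((2, 2, 1), 0.5)
        assert fledgling_loglik(tab, fled) == 0.0

    def test_closed_form(self):
        tab = FledglingTable.from_records([(0, 0, 0, 1, 3)])
        fled = np.full((2, 2, 1), 1.5)
        # F - S = 2 with rate S*(2*1.5-1) = 2
        assert fledgling_loglik(tab, fled) == pytest.approx(
            np.log(2.0 * np.exp(-2.0)))

    def test_matches_scipy_poisson_oracle(self):
        rng = np.random.default_rng(1)
        T = 24
        fled = rng.uniform(0.7, 2.0, (2, 2, T))
        rows = []
        expected = 0.0
        for t in range(T):
            for a in range(2):
                for h in range(2):
                    S = int(rng.integers(0, 25))
                    F = S + int(rng.integers(0, 40)) if S else 0
                    rows.append((t, a, h, S, F))
                    if S:
                        expected += stats.poisson.logpmf(
                            F - S, S * (2 * fled[a, h, t] - 1))
        got = fledgling_loglik(FledglingTable.from_records(rows), fled)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_fewer_fledglings_than_broods_rejected(self):
        with pytest.raises(ValueError):
            FledglingTable.from_records([(0, 0, 0, 3, 2)])


class TestTransitionMatrices:
    def test_no_survival_all_dead(self):
        par = random_params_list(2, 2)[0]
        par.phi_succ[:] = 0.0
        par.phi_fail[:] = 0.0
        M = build_adult_transition_matrix(par, par)
        assert np.allclose(M[:8, 8], 1.0)
        assert np.allclose(M[:8, :8], 0.0)

    def test_certain_survival_and_success(self):
        par = random_params_list(3, 2)[0]
        par.phi_succ[:] = 1.0
        par.phi_fail[:] = 1.0
        par.psi_succ = np.eye(2)
        par.psi_fail = np.eye(2)
        nxt = par.copy()
        nxt.b[1, :] = 1.0
        M = build_adult_transition_matrix(par, nxt)
        for a in range(2):
            for h in range(2):
                for s in range(2):
                    i = 4 * a + 2 * h + s
                    j = 4 + 2 * h  # Old, same habitat, successful
                    assert M[i, j] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_row_stochastic_and_path_oracle(self, seed):
        par, nxt = random_params_list(seed, 2)
        M = build_adult_transition_matrix(par, nxt)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        # brute-force enumeration of survive x move x next-success paths
        for a in range(2):
            for h in range(2):
                for s in range(2):
                    i = 4 * a + 2 * h + s
                    phi = (par.phi_succ if s == 0 else par.phi_fail)[a, h]
                    psi = (par.psi_succ if s == 0 else par.psi_fail)[h]
                    for h2 in range(2):
                        for s2 in range(2):
                            b2 = nxt.b[1, h2]
                            expect = phi * psi[h2] * (b2 if s2 == 0
                                                      else 1 - b2)
                            assert M[i, 4 + 2 * h2 + s2] == pytest.approx(
                                expect, abs=1e-14)
                    assert M[i, 8] == pytest.approx(1 - phi, abs=1e-14)

    def test_observation_degenerate_cases(self):
        O = build_observation_matrix(0.0, 0.7)
        assert np.allclose(O[:, 0], 1.0)
        O = build_observation_matrix(1.0, 1.0)
        for a in range(2):
            for h in range(2):
                for s in range(2):
                    assert O[4 * a + 2 * h + s, 1 + 3 * h + s] == 1.0
        assert O[8, 0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_observation_row_stochastic_and_entries(self, seed):
        rng = np.random.default_rng(seed)
        p, c = rng.uniform(0, 1, 2)
        O = build_observation_matrix(p, c)
        assert np.allclose(O.sum(axis=1), 1.0, atol=1e-12)
        assert O[0, 0] == pytest.approx(1 - p)
        assert O[5, 1 + 3 * 0 + 1] == pytest.approx(p * c)  # (O,S,fail)
        assert O[6, 6] == pytest.approx(p * (1 - c))        # (O,T,succ) unk


def enumerate_history_loglik(first_state, first_year, events, params):
    """Independent oracle: explicit sum over all hidden-state paths."""
    T = len(params)
    trans = [build_adult_transition_matrix(params[t], params[t + 1])
             for t in range(T - 1)]
    obs = build_observation_matrix(params[0].p, params[0].c)
    steps = list(range(first_year, T - 1))
    total = 0.0
    for path in itertools.product(range(9), repeat=len(steps)):
        prob = 1.0
        s_prev = first_state
        for k, t in enumerate(steps):
            s_next = path[k]
            prob *= trans[t][s_prev, s_next] * obs[s_next, events[t + 1]]
            s_prev = s_next
        total += prob
    return np.log(total)


class TestAdultMultiEvent:
    def test_single_certain_path(self):
        par, nxt = random_params_list(11, 2)
        par.p = 1.0
        par.c = 1.0
        nxt.p = 1.0
        nxt.c = 1.0
        # released (O,S,succ), seen next year as (O,S,succ): one path
        h = AdultHistories(first_year=[0], first_state=[4],
                           events=[[0, 1]], n_years=2)
        got = adult_multievent_loglik(h, [par, nxt])
        expect = np.log(par.phi_succ[1, 0] * par.psi_succ[0, 0]
                        * nxt.b[1, 0])
        assert got == pytest.approx(expect, abs=1e-12)

    def test_certain_death_certain_silence(self):
        par, nxt = random_params_list(12, 2)
        par.phi_succ[:] = 0.0
        par.phi_fail[:] = 0.0
        h = AdultHistories(first_year=[0], first_state=[0],
                           events=[[0, 0]], n_years=2)
        assert adult_multievent_loglik(h, [par, nxt]) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_forward_equals_path_enumeration(self, seed):
        params = random_params_list(100 + seed, 4)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            fy = int(rng.integers(0, 3))
            fs = int(rng.integers(0, 8))
            ev = np.zeros(4, dtype=int)
            ev[fy + 1:] = rng.integers(0, 7, 3 - fy)
            h = AdultHistories(first_year=[fy], first_state=[fs],
                               events=[ev], n_years=4)
            got = adult_multievent_loglik(h, params)
            expect = enumerate_history_loglik(fs, fy, ev, params)
            assert got == pytest.approx(expect, abs=1e-10)


class TestJuvenileRecruitment:
    def test_zero_recruitment(self):
        h = JuvenileHistories(natal_habitat=[0, 1], birth_year=[0, 1],
                              event=[0, 0], n_years=3)
        phi = np.zeros((2, 2))
        psi = np.array([[0.7, 0.3], [0.4, 0.6]])
        assert juvenile_recruitment_loglik(h, phi, psi, 0.9) == 0.0

    def test_certain_recruitment_home(self):
        h = JuvenileHistories(natal_habitat=[0], birth_year=[0],
                              event=[1], n_years=3)
        phi = np.ones((2, 2))
        assert juvenile_recruitment_loglik(h, phi, np.eye(2), 1.0) == \
            pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        T = 5
        phi = rng.uniform(0.05, 0.6, (2, T - 1))
        s = rng.uniform(0.2, 0.8, 2)
        psi = np.column_stack([s, 1 - s])
        p = rng.uniform(0.5, 1.0)
        nh = rng.integers(0, 2, 30)
        by = rng.integers(0, T - 1, 30)
        ev = rng.integers(0, 3, 30)
        h = JuvenileHistories(natal_habitat=nh, birth_year=by, event=ev,
                              n_years=T)
        expected = 0.0
        for i in range(30):
            f = phi[nh[i], by[i]]
            # enumerate (recruit?, where, detected?) outcomes
            pr = {0: (1 - f) + f * (1 - p),
                  1: f * psi[nh[i], 0] * p,
                  2: f * psi[nh[i], 1] * p}
            expected += np.log(pr[ev[i]])
        got = juvenile_recruitment_loglik(h, phi, psi, p)
        assert got == pytest.approx(expected, abs=1e-10)


class TestCountStateSpace:
    def _params(self, seed, T):
        return random_params_list(seed, T)

    def test_no_survival_no_immigration_forces_zero(self):
        T = 3
        params = self._params(21, T)
        for par in params:
            par.phi_fl[:] = 0.0
            par.phi_succ[:] = 0.0
            par.phi_fail[:] = 0.0
        latent = CountLatentState(
            n0=[5, 5, 5, 5], recruits=np.zeros((2, 2, T - 1)),
            adult_flows=np.zeros((4, 2, T - 1)),
            immigrants=np.zeros((4, T - 1)))
        imm_means = np.zeros((4, T - 1))
        ll = count_state_space_loglik(None, latent, params, imm_means)
        assert np.isfinite(ll)
        # a positive latent inflow is impossible
        latent2 = CountLatentState(
            n0=[5, 5, 5, 5], recruits=np.zeros((2, 2, T - 1)),
            adult_flows=np.zeros((4, 2, T - 1)),
            immigrants=np.eye(4, T - 1))
        assert count_state_space_loglik(None, latent2, params,
                                        imm_means) == -np.inf

    def test_observation_maximized_at_latent_counts(self):
        T = 2
        params = self._params(22, T)
        latent = CountLatentState(
            n0=[8, 6, 12, 9], recruits=np.ones((2, 2, 1)) * 2,
            adult_flows=np.ones((4, 2, 1)) * 3,
            immigrants=np.ones((4, 1)))
        imm = np.ones((4, 1))
        nb = latent.nb_trajectory()

        def ll_with_counts(y):
            rows = [(t, k // 2, k % 2, int(y[k, t]))
                    for t in range(T) for k in range(4)]
            return count_state_space_loglik(CountTable.from_records(rows),
                                            latent, params, imm)

        base = ll_with_counts(nb)
        for dk in (-2, -1, 1, 2):
            y = nb.copy()
            y[0, 0] = max(nb[0, 0] + dk, 0)
            assert ll_with_counts(y) <= base

    def test_moment_matching_against_projection(self):
        # the expected latent trajectory equals the deterministic projection
        T = 2
        params = self._params(23, T)
        par = params[0]
        nb0 = np.array([300.0, 200.0, 400.0, 250.0])
        A = hp.build_projection_matrix(par)
        imm_mean = np.array([[5.0], [3.0], [4.0], [2.0]])
        expected = A @ nb0 + imm_mean[:, 0]
        # build the latent state at its expected values
        rec = np.zeros((2, 2, 1))
        for h in range(2):
            rate = sum(nb0[2 * a + h] * par.b[a, h] * par.fled[a, h]
                       * par.phi_fl[h] for a in range(2))
            rec[h, :, 0] = rate * par.psi_fl[h]
        afl = np.zeros((4, 2, 1))
        for k in range(4):
            a, h = divmod(k, 2)
            for h2 in range(2):
                afl[k, h2, 0] = nb0[k] * (
                    par.b[a, h] * par.phi_succ[a, h] * par.psi_succ[h, h2]
                    + (1 - par.b[a, h]) * par.phi_fail[a, h]
                    * par.psi_fail[h, h2])
        latent = CountLatentState(n0=nb0, recruits=rec, adult_flows=afl,
                                  immigrants=imm_mean.copy())
        assert np.allclose(latent.nb_trajectory()[:, 1], expected, atol=1e-9)

    def test_joint_loglik_is_sum_of_submodels(self, default_dataset):
        # shared-parameter wiring: the joint equals the four components
        tr = default_dataset.truth
        obs = default_dataset.observed
        latent = CountLatentState(
            n0=tr.nb[:, 0], recruits=tr.recruits_by_origin,
            adult_flows=tr.adult_flows, immigrants=tr.immigrants)
        params = tr.params
        b = np.stack([p.b for p in params], axis=-1)
        fled = np.stack([p.fled for p in params], axis=-1)
        phi_fl = np.stack([p.phi_fl for p in params[:-1]], axis=-1)
        parts = [
            breeding_success_loglik(obs.breeding, b),
            fledgling_loglik(obs.fledgling, fled),
            adult_multievent_loglik(obs.adults, params),
            juvenile_recruitment_loglik(obs.juveniles, phi_fl,
                                        params[0].psi_fl, params[0].p),
            count_state_space_loglik(obs.counts, latent, params,
                                     tr.imm_means),
        ]
        total = hp.joint_loglik(obs, params, latent, tr.imm_means)
        assert np.isfinite(total)
        assert total == pytest.approx(sum(parts), abs=1e-8)


class TestKernelAgreement:
    def test_numba_cmr_matches_reference(self, default_dataset):
        # the compiled forward pass used by the sampler must agree with the
        # plain reference implementation
        from habitatipm import _kernels as K
        from habitatipm.fit import _prepare_arrays
        obs = default_dataset.observed
        params = default_dataset.truth.params
        (R, B, S, F, fy, fs, ev, lo, wt, J, y,
         has_counts) = _prepare_arrays(obs)
        T = obs.n_years
        nat = np.zeros((18, T))
        for t, par in enumerate(params):
            nat[0:4, t] = par.b.ravel()
            nat[4:8, t] = par.fled.ravel()
            if t < T - 1:
                nat[8:10, t] = par.phi_fl
                nat[10:14, t] = par.phi_succ.ravel()
                nat[14:18, t] = par.phi_fail.ravel()
        par = params[0]
        psi_lin = np.concatenate([
            np.log(par.psi_fl[:, 0] / (1 - par.psi_fl[:, 0])),
            np.log(par.psi_succ[:, 0] / (1 - par.psi_succ[:, 0])),
            np.log(par.psi_fail[:, 0] / (1 - par.psi_fail[:, 0]))])
        got = K.ll_cmr(nat, psi_lin, par.p, par.c, fy, fs, ev, lo, wt, T)
        ref = adult_multievent_loglik(obs.adults, params)
        assert got == pytest.approx(ref, abs=1e-8)
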