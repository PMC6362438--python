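"""Joint posterior assembly, MCMC fitting, convergence diagnostics and
posterior summaries for the integrated population model.

The posterior joins four submodels (breeding success, fledgling counts,
adult multi-event mark--resight, fledgling recruitment) and the count
state-space model with apparent immigration under shared parameters.
Sampling uses the package's adaptive Metropolis-within-Gibbs engine
(:mod:`habitatipm._kernels`); the contract is posterior correctness plus a
Gelman--Rubin statistic below 1.1, not a particular engine.  Hidden CMR
states are marginalized exactly by the forward algorithm; the integer
latent flows of the count process are sampled.

Default chain settings are test-scale (3 chains, 3,000 iterations with a
1,000-iteration burn-in, no thinning); ``scale="reporting"`` switches to
the full reporting-scale settings (30,000 kept iterations after a 10,000
burn-in, thinning 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .core import CLASS_LABELS, N_CLASSES
from .likelihoods import ObservedDataset

#: parameter-family names in kernel order (b, fled, phi_fl, phi_succ, phi_fail)
FAMILY_NAMES = (
    "b_Y_S", "b_Y_T", "b_O_S", "b_O_T",
    "fled_Y_S", "fled_Y_T", "fled_O_S", "fled_O_T",
    "phi_fl_S", "phi_fl_T",
    "phi_succ_Y_S", "phi_succ_Y_T", "phi_succ_O_S", "phi_succ_O_T",
    "phi_fail_Y_S", "phi_fail_Y_T", "phi_fail_O_S", "phi_fail_O_T",
)
PSI_NAMES = ("psi_fl_S_S", "psi_fl_T_S", "psi_succ_S_S", "psi_succ_T_S",
             "psi_fail_S_S", "psi_fail_T_S")


def _logit(x):
    x = np.clip(x, 1e-6, 1 - 1e-6)
    return np.log(x / (1 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PriorSpec:
    """Prior hyperparameters for the joint model.

    Link-scale means get Normal(0, 1/sqrt(0.001)); temporal SDs Uniform(0,
    10); resighting and state-certainty probabilities Uniform(0, 1);
    expected yearly immigrant numbers Uniform(-5, 20) per class-year (the
    latent Poisson rate is max(mean, 0), so the negative range carries
    prior mass onto "no immigration"); initial latent class sizes
    Normal(first-year count, 1/sqrt(0.01)) truncated at zero.
    """

    mean_sd: float = 1.0 / np.sqrt(0.001)
    sigma_max: float = 10.0
    imm_lower: float = -5.0
    imm_upper: float = 20.0
    n0_sd: float = 1.0 / np.sqrt(0.01)

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_sd, self.sigma_max, self.imm_lower,
                         self.imm_upper, self.n0_sd])


@dataclass
class PosteriorDraws:
    """Joint posterior samples, dimensions (chain, draw, ...)."""

    nat: np.ndarray        # (C, S, 18, T) natural-scale annual rates
    mu: np.ndarray         # (C, S, 18) link-scale means
    sigma: np.ndarray      # (C, S, 18) link-scale temporal SDs
    psi_lin: np.ndarray    # (C, S, 6) stay/settle-in-S logits
    pc: np.ndarray         # (C, S, 2) resighting p and certainty c
    imm_mean: np.ndarray   # (C, S, 4, T-1) expected immigrant numbers
    n0: np.ndarray         # (C, S, 4)
    recruits: np.ndarray   # (C, S, 2, 2, T-1)
    adult_flows: np.ndarray  # (C, S, 4, 2, T-1)
    immigrants: np.ndarray   # (C, S, 4, T-1)
    loglik: np.ndarray       # (C, S)
    n_years: int
    seed: int = 0

    @property
    def n_chains(self) -> int:
        return self.nat.shape[0]

    @property
    def n_draws(self) -> int:
        return self.nat.shape[1]

    def series(self, name: str) -> np.ndarray:
        """(C, S, n_years) realized annual values of one parameter family."""
        f = FAMILY_NAMES.index(name)
        ny = self.n_years if f < 8 else self.n_years - 1
        return self.nat[:, :, f, :ny]

    def psi_matrix(self, which: str) -> np.ndarray:
        """(C, S, 2, 2) transition matrices for 'fl', 'succ' or 'fail'."""
        off = {"fl": 0, "succ": 2, "fail": 4}[which]
        pS = _expit(self.psi_lin[:, :, off:off + 2])
        return np.stack([pS, 1.0 - pS], axis=-1)

    def nb(self) -> np.ndarray:
        """(C, S, 4, T) latent breeder counts implied by the flows."""
        T = self.n_years
        nb = np.zeros(self.n0.shape[:2] + (N_CLASSES, T))
        nb[..., 0] = self.n0
        nb[..., :2, 1:] = (self.recruits.sum(axis=2)
                           + self.immigrants[..., :2, :])
        nb[..., 2:, 1:] = (self.adult_flows.sum(axis=2)
                           + self.immigrants[..., 2:, :])
        return nb

    def lambda_t(self) -> np.ndarray:
        """(C, S, T-1) realized annual growth rates of the latent totals."""
        tot = self.nb().sum(axis=2)
        return tot[..., 1:] / tot[..., :-1]

    def omega_t(self) -> np.ndarray:
        """(C, S, 4, T-1) realized per-capita apparent immigration: the
        immigrants joining at t+1 relative to the total population at t."""
        tot = self.nb().sum(axis=2)
        return self.immigrants / tot[..., None, :-1]

    def flatten(self, x: np.ndarray) -> np.ndarray:
        """Merge chain and draw axes."""
        return x.reshape((-1,) + x.shape[2:])


def _prepare_arrays(dataset: ObservedDataset):
    T = dataset.n_years
    R = np.zeros((N_CLASSES, T))
    B = np.zeros((N_CLASSES, T))
    for _, r in dataset.breeding.df.iterrows():
        k = 2 * int(r.age) + int(r.habitat)
        R[k, int(r.year)] += r.n_monitored
        B[k, int(r.year)] += r.n_successful
    S = np.zeros((N_CLASSES, T))
    F = np.zeros((N_CLASSES, T))
    for _, r in dataset.fledgling.df.iterrows():
        k = 2 * int(r.age) + int(r.habitat)
        S[k, int(r.year)] += r.n_known
        F[k, int(r.year)] += r.total_fledglings
    # aggregate identical adult histories; the forward pass is the sampler's
    # hot loop and duplicated capture patterns are common
    ad = dataset.adults
    if len(ad):
        key = np.column_stack([ad.first_year, ad.first_state, ad.events])
        uniq, inv, cnt = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        fy = uniq[:, 0].astype(np.int64)
        fs = uniq[:, 1].astype(np.int64)
        ev = np.ascontiguousarray(uniq[:, 2:]).astype(np.int64)
        wt = cnt.astype(float)
    else:
        fy = np.zeros(0, dtype=np.int64)
        fs = np.zeros(0, dtype=np.int64)
        ev = np.zeros((0, T), dtype=np.int64)
        wt = np.zeros(0)
    lo = _last_occasions(fy, ev)
    J = np.zeros((2, T - 1, 3))
    jv = dataset.juveniles
    for h, by, e in zip(jv.natal_habitat, jv.birth_year, jv.event):
        J[h, by, e] += 1.0
    if dataset.counts is not None:
        y = dataset.counts.to_array(T)
        has_counts = True
    else:
        y = np.zeros((N_CLASSES, T))
        has_counts = False
    return R, B, S, F, fy, fs, ev, lo, wt, J, y, has_counts


def _last_occasions(fy: np.ndarray, ev: np.ndarray) -> np.ndarray:
    """Last occasion with a sighting per history (release year if none)."""
    lo = fy.copy()
    for i in range(len(fy)):
        nz = np.nonzero(ev[i])[0]
        nz = nz[nz > fy[i]]
        if len(nz):
            lo[i] = nz[-1]
    return lo.astype(np.int64)


def _initial_state(R, B, S, F, J, y, has_counts, T, rng, jitter=0.0):
    """Moment-style initial values; ``jitter`` perturbs them on retries."""
    mu = np.zeros(K.NF)
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in range(4):
            tot_R, tot_B = R[k].sum(), B[k].sum()
            mu[k] = _logit(tot_B / tot_R if tot_R > 0 else 0.6)
            tot_S, tot_F = S[k].sum(), F[k].sum()
            fl = (tot_F / tot_S / 2.0) if tot_S > 0 else 1.2
            mu[4 + k] = np.log(max(fl, 0.6))
        for h in range(2):
            seen = J[h, :, 1:].sum()
            tot = J[h].sum()
            mu[8 + h] = _logit(min(max(seen / tot / 0.9, 0.01), 0.5)
                               if tot > 0 else 0.08)
    mu[10:14] = _logit(0.45)
    mu[14:18] = _logit(0.35)
    sigma = np.full(K.NF, 0.2)
    z = np.zeros((K.NF, T))
    psi = np.array([_logit(0.8), _logit(0.5), _logit(0.85), _logit(0.2),
                    _logit(0.7), _logit(0.4)])
    p, c = 0.9, 0.9
    if jitter > 0:
        mu = mu + rng.normal(0, jitter, mu.shape)
        psi = psi + rng.normal(0, jitter, psi.shape)

    # latent flows consistent with the counts: walk the counts forward and
    # absorb the residual into the immigrants
    nat = np.zeros((K.NF, T))
    for f in range(K.NF):
        x = mu[f] + sigma[f] * z[f]
        nat[f] = np.exp(x) if 4 <= f < 8 else _expit(x)
    y_eff = y if has_counts else np.tile(
        np.array([[20.0], [15.0], [35.0], [20.0]]), (1, T))
    n0 = np.maximum(y_eff[:, 0], 1.0)
    rec = np.zeros((2, 2, T - 1))
    afl = np.zeros((4, 2, T - 1))
    imm = np.zeros((4, T - 1))
    nb = n0.copy()
    psiS = _expit(psi)
    for t in range(T - 1):
        for h in range(2):
            rate = sum(nb[2 * a + h] * nat[2 * a + h, t]
                       * nat[4 + 2 * a + h, t] * nat[8 + h, t]
                       for a in range(2))
            rec[h, 0, t] = np.floor(rate * psiS[h])
            rec[h, 1, t] = np.floor(rate * (1 - psiS[h]))
        for k in range(4):
            a, h = divmod(k, 2)
            bb = nat[2 * a + h, t]
            q0 = (bb * nat[10 + k, t] * psiS[2 + h]
                  + (1 - bb) * nat[14 + k, t] * psiS[4 + h])
            q1 = (bb * nat[10 + k, t] * (1 - psiS[2 + h])
                  + (1 - bb) * nat[14 + k, t] * (1 - psiS[4 + h]))
            afl[k, 0, t] = np.floor(nb[k] * q0)
            afl[k, 1, t] = np.floor(nb[k] * q1)
        local = np.array([rec[:, 0, t].sum(), rec[:, 1, t].sum(),
                          afl[:, 0, t].sum(), afl[:, 1, t].sum()])
        imm[:, t] = np.maximum(np.round(y_eff[:, t + 1]) - local, 0.0)
        nb = local + imm[:, t]
        if nb.sum() <= 0:
            nb = np.ones(4)
            imm[:, t] += 1.0
    imm_mean = np.clip(imm, 0.0, 19.5)
    return mu, sigma, z, psi, p, c, imm_mean, n0, rec, afl, imm


def fit_ipm(dataset: ObservedDataset, priors: PriorSpec | None = None,
            chains: int = 3, iterations: int = 3000, burnin: int = 1000,
            thin: int = 1, seed: int = 0,
            scale: str = "test") -> PosteriorDraws:
    """Fit the IPM by MCMC and return joint posterior draws.

    ``iterations`` counts post-burn-in iterations per chain.  With
    ``scale="reporting"`` the chain settings switch to 30,000 kept iterations
    after a 10,000 burn-in with thinning 3.  Initialization is moment-based
    with bounded re-initialization retries if the joint density is not
    finite at the starting point.
    """
    if priors is None:
        priors = PriorSpec()
    if scale == "reporting":
        iterations, burnin, thin = 30000, 10000, 3
    T = dataset.n_years
    R, B, S, F, fy, fs, ev, lo, wt, J, y, has_counts = _prepare_arrays(dataset)
    pri = priors.as_array()
    rng = np.random.default_rng(seed)

    init = None
    for attempt in range(6):
        cand = _initial_state(R, B, S, F, J, y, has_counts, T, rng,
                              jitter=0.1 * attempt)
        mu, sigma, z, psi, p, c, imm_mean, n0, rec, afl, imm = cand
        nat = np.zeros((K.NF, T))
        for f in range(K.NF):
            x = mu[f] + sigma[f] * z[f]
            nat[f] = np.exp(x) if 4 <= f < 8 else _expit(x)
        L = np.zeros(6)
        K._components(nat, psi, p, c, imm_mean, mu, sigma, z, n0, rec, afl,
                      imm, R, B, S, F, fy, fs, ev, lo, wt, J, y, y[:, 0],
                      has_counts, T, np.ones(5, dtype=np.int64), L, pri)
        if np.isfinite(L.sum()):
            init = cand
            break
    if init is None:
        raise RuntimeError("could not find a finite starting point after "
                           "6 re-initialization attempts")
    mu, sigma, z, psi, p, c, imm_mean, n0, rec, afl, imm = init

    out = []
    n_iter = burnin + iterations
    for ch in range(chains):
        chain_seed = int(rng.integers(1, 2 ** 31 - 1))
        out.append(K.run_chain(
            chain_seed, n_iter, burnin, thin,
            R, B, S, F, fy, fs, ev, lo, wt, J, y, y[:, 0], has_counts, T,
            mu, sigma, z, psi, p, c, imm_mean, n0, rec, afl, imm, pri))
    stack = [np.stack([o[i] for o in out]) for i in range(11)]
    return PosteriorDraws(
        nat=stack[0], mu=stack[1], sigma=stack[2], psi_lin=stack[3],
        pc=stack[4], imm_mean=stack[5], n0=stack[6], recruits=stack[7],
        adult_flows=stack[8], immigrants=stack[9], loglik=stack[10],
        n_years=T, seed=seed)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray) -> float:
    """Split Gelman--Rubin potential scale reduction for one scalar.

    ``x`` is (chains, draws); each chain is split in half, and the statistic
    is ``sqrt(((n-1)/n * W + B/n) / W)`` over the split chains.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    n = splits.shape[1]
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    Bv = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + Bv / n) / W))


def rhat_diagnostic(draws: PosteriorDraws, threshold: float = 1.1):
    """Split-R-hat for the reported scalar summaries.

    Covers link-scale means and SDs, transition logits, p, c, each family's
    across-year mean rate, and the yearly immigrant totals.  Returns a
    Series; values above ``threshold`` indicate non-convergence.
    """
    if draws.n_chains < 2:
        raise ValueError("R-hat needs at least two chains")
    stats = {}
    for f, name in enumerate(FAMILY_NAMES):
        stats[f"mu_{name}"] = split_rhat(draws.mu[:, :, f])
        stats[f"sigma_{name}"] = split_rhat(draws.sigma[:, :, f])
        stats[f"mean_{name}"] = split_rhat(draws.series(name).mean(axis=-1))
    for j, name in enumerate(PSI_NAMES):
        stats[name] = split_rhat(draws.psi_lin[:, :, j])
    stats["p"] = split_rhat(draws.pc[:, :, 0])
    stats["c"] = split_rhat(draws.pc[:, :, 1])
    stats["imm_total"] = split_rhat(draws.immigrants.sum(axis=(2, 3)))
    return pd.Series(stats)


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def _chisq(obs, exp, var):
    var = np.maximum(var, 0.5)
    return float(np.sum((obs - exp) ** 2 / var))


def posterior_predictive_check(draws: PosteriorDraws,
                               dataset: ObservedDataset,
                               n_rep: int = 200,
                               seed: int = 0) -> pd.Series:
    """Bayesian p-values per submodel from replicate datasets.

    Chi-square-style discrepancies for the binomial, shifted-Poisson and
    count submodels; a deviance discrepancy for the two mark--resight
    submodels (replicate histories are simulated from each draw's hidden
    process).  Values near 0 or 1 flag misfit.
    """
    rng = np.random.default_rng(seed)
    T = draws.n_years
    R, B, S, F, fy, fs, ev, lo, wt, J, y, has_counts = _prepare_arrays(dataset)
    C, D = draws.n_chains, draws.n_draws
    idx = [(rng.integers(C), rng.integers(D)) for _ in range(n_rep)]

    wins = {k: 0 for k in ("breeding", "fledgling", "counts", "adult_cmr",
                           "juvenile")}
    for ci, di in idx:
        nat = draws.nat[ci, di]
        # breeding: binomial chi-square
        bmat = np.array([nat[2 * a + h] for a in range(2) for h in range(2)])
        exp_B = R * bmat
        var_B = R * bmat * (1 - bmat)
        B_rep = rng.binomial(R.astype(int), bmat)
        if _chisq(B_rep, exp_B, var_B) >= _chisq(B, exp_B, var_B):
            wins["breeding"] += 1
        # fledglings: shifted Poisson
        rate = S * (2 * nat[4:8] - 1)
        F_rep = S + rng.poisson(np.maximum(rate, 0.0))
        if _chisq(F_rep, S + rate, rate) >= _chisq(F, S + rate, rate):
            wins["fledgling"] += 1
        # counts: Poisson observation around the latent states
        if has_counts:
            nb = draws.nb()[ci, di]
            y_rep = rng.poisson(nb)
            if _chisq(y_rep, nb, nb) >= _chisq(y, nb, nb):
                wins["counts"] += 1
        # adult CMR: deviance of observed vs replicate histories
        psi = draws.psi_lin[ci, di]
        p, c = draws.pc[ci, di]
        ev_rep = _simulate_adult_events(nat, psi, p, c, fy, fs, wt, T, rng)
        d_obs = -2.0 * K.ll_cmr(nat, psi, p, c, fy, fs, ev, lo, wt, T)
        d_rep = -2.0 * K.ll_cmr(nat, psi, p, c, ev_rep[0], ev_rep[1],
                                ev_rep[2], _last_occasions(ev_rep[0],
                                                           ev_rep[2]),
                                ev_rep[3], T)
        if d_rep >= d_obs:
            wins["adult_cmr"] += 1
        # juveniles: multinomial deviance on the event counts
        J_rep = np.zeros_like(J)
        for h in range(2):
            psiS = _expit(psi[h])
            for t in range(T - 1):
                n = int(J[h, t].sum())
                if n == 0:
                    continue
                fl = nat[8 + h, t]
                pr = np.array([1 - fl * p, fl * psiS * p,
                               fl * (1 - psiS) * p])
                J_rep[h, t] = rng.multinomial(n, pr / pr.sum())
        d_obs = -2.0 * K.ll_juvenile(nat, psi, p, J, T)
        d_rep = -2.0 * K.ll_juvenile(nat, psi, p, J_rep, T)
        if d_rep >= d_obs:
            wins["juvenile"] += 1

    out = {k: (v + 0.5) / (n_rep + 1) for k, v in wins.items()
           if k != "counts" or has_counts}
    return pd.Series(out)


def _simulate_adult_events(nat, psi, p, c, fy, fs, wt, T, rng):
    """Replicate adult histories (expanded to individuals) from one draw."""
    trans = np.empty((T - 1, 9, 9))
    K.build_transitions(nat, psi, T, trans)
    obs = np.empty((9, 7))
    K.build_observation(p, c, obs)
    fy_out, fs_out, ev_out = [], [], []
    for i in range(len(fy)):
        for _ in range(int(wt[i])):
            state = fs[i]
            events = np.zeros(T, dtype=np.int64)
            for t in range(fy[i], T - 1):
                state = rng.choice(9, p=trans[t, state])
                events[t + 1] = rng.choice(7, p=obs[state])
            fy_out.append(fy[i])
            fs_out.append(fs[i])
            ev_out.append(events)
    return (np.array(fy_out, dtype=np.int64), np.array(fs_out, dtype=np.int64),
            np.stack(ev_out) if ev_out else np.zeros((0, T), dtype=np.int64),
            np.ones(len(fy_out)))


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def _mean_ci(x: np.ndarray):
    return (float(np.mean(x)), float(np.quantile(x, 0.025)),
            float(np.quantile(x, 0.975)))


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Report-style posterior summary table.

    For every year-varying parameter: the posterior of its across-year
    arithmetic mean and of its temporal CV (sd/mean of the realized annual
    values within each draw).  Also the class proportions ``n``, per-capita
    immigration rates ``omega`` (and their total), both-sex fledgling
    numbers ``f = 2 * fled``, transition probabilities, p, c, annual-growth
    geometric mean, and habitat productivities (geometric means).
    """
    rows = []

    def add(name, mean_samples, cv_samples=None):
        m, lo, hi = _mean_ci(mean_samples)
        row = {"parameter": name, "mean": m, "lo": lo, "hi": hi,
               "cv": np.nan, "cv_lo": np.nan, "cv_hi": np.nan}
        if cv_samples is not None:
            row["cv"], row["cv_lo"], row["cv_hi"] = _mean_ci(cv_samples)
        rows.append(row)

    nb = draws.nb()
    tot = nb.sum(axis=2)
    # class proportions across years
    for k, lab in enumerate(CLASS_LABELS):
        prop = nb[:, :, k, :] / tot
        add(f"n_{lab}", prop.mean(axis=-1),
            prop.std(axis=-1, ddof=0) / prop.mean(axis=-1))
    for f, name in enumerate(FAMILY_NAMES):
        ser = draws.series(name)
        mean_t = ser.mean(axis=-1)
        cv_t = ser.std(axis=-1, ddof=0) / mean_t
        add(name, mean_t, cv_t)
        if name.startswith("fled"):
            add("f" + name[4:], 2.0 * mean_t, cv_t)
    om = draws.omega_t()
    for k, lab in enumerate(CLASS_LABELS):
        ser = om[:, :, k, :]
        add(f"omega_{lab}", ser.mean(axis=-1),
            ser.std(axis=-1, ddof=0) / np.maximum(ser.mean(axis=-1), 1e-9))
    add("omega_total", om.sum(axis=2).mean(axis=-1))
    for j, name in enumerate(PSI_NAMES):
        add(name, _expit(draws.psi_lin[:, :, j]))
    add("p", draws.pc[:, :, 0])
    add("c", draws.pc[:, :, 1])
    lam = draws.lambda_t()
    add("lambda_geometric_mean", np.exp(np.log(lam).mean(axis=-1)))
    prod = productivity_series(draws)
    for h, lab in enumerate(("S", "T")):
        ser = prod[:, :, h, :]
        add(f"productivity_{lab}",
            np.exp(np.log(np.maximum(ser, 1e-9)).mean(axis=-1)),
            ser.std(axis=-1, ddof=0) / np.maximum(ser.mean(axis=-1), 1e-9))
    return pd.DataFrame(rows).set_index("parameter")


def productivity_series(draws: PosteriorDraws) -> np.ndarray:
    """(C, S, 2, T-1) habitat productivity per draw and transition year:
    (first-year recruits originating from the habitat + apparently surviving
    adults from the habitat) / breeders in the habitat."""
    nb = draws.nb()
    out = np.zeros(nb.shape[:2] + (2, draws.n_years - 1))
    for h in range(2):
        origin = draws.recruits[:, :, h, :, :].sum(axis=2)
        surv = draws.adult_flows[:, :, [h, 2 + h], :, :].sum(axis=(2, 3))
        adults = np.maximum(nb[:, :, [h, 2 + h], :-1].sum(axis=2), 1e-9)
        out[:, :, h, :] = (origin + surv) / adults
    return out
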