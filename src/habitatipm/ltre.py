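"""Transient life-table response experiment (LTRE) for the realized growth.

The realized annual growth rate is written as a function of that year's
demographic parameters, population structure and per-capita apparent
immigration,

    lambda_t = sum_j colsum_j(A(theta_t)) * n_{j,t} + sum_k omega_{k,t},

where ``A`` is the annual projection matrix, ``n`` the class-proportion
vector and ``omega`` the class-specific immigrants joining at t+1 per
individual present at t.  The retrospective decomposition attributes the
temporal variance of lambda to each argument via first-order sensitivities
evaluated at the across-year means:

    contribution_i = sum_j cov(theta_i, theta_j) * s_i * s_j,

so that the contributions sum to the first-order approximation of
var(lambda_t), covariation between parameters included.  Year-specific
contributions are Delta(theta_i) between consecutive years times the
sensitivity at the earlier year.  Everything is computed per posterior draw
and summarized with means and equal-tailed 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnualParams, CLASS_LABELS
from .fit import FAMILY_NAMES, PSI_NAMES, PosteriorDraws

#: full LTRE argument vector: 18 vital-rate families, 6 transition
#: probabilities (constant in time), 4 structure proportions, 4 per-capita
#: immigration rates
LTRE_PARAM_NAMES = (FAMILY_NAMES + PSI_NAMES
                    + tuple(f"n_{lab}" for lab in CLASS_LABELS)
                    + tuple(f"omega_{lab}" for lab in CLASS_LABELS))
N_PARAMS = len(LTRE_PARAM_NAMES)

_GROUPS = {}
for _name in LTRE_PARAM_NAMES:
    if _name.startswith("n_"):
        _GROUPS[_name] = "structure"
    elif _name.startswith("omega_"):
        _GROUPS[_name] = "immigration"
    elif _name.endswith("_S") or "_S_" in _name[-4:]:
        _GROUPS[_name] = "short_demography"
    else:
        _GROUPS[_name] = "tall_demography"
# transition probabilities grouped by habitat of origin
for _j, _name in enumerate(PSI_NAMES):
    _GROUPS[_name] = ("short_demography" if _name.split("_")[-2] == "S"
                      else "tall_demography")
GROUP_OF = dict(_GROUPS)
GROUP_ORDER = ("short_demography", "tall_demography", "structure",
               "immigration")


@dataclass
class RealizedSeries:
    """Realized annual LTRE arguments for one posterior draw (or the truth).

    ``theta`` is (N_PARAMS, T-1): one column per transition year, in the
    order of :data:`LTRE_PARAM_NAMES`.  ``state0`` and ``immigrants`` carry
    what deterministic re-propagation needs (year-1 class counts and the
    immigrant numbers joining at each later year).
    """

    theta: np.ndarray
    state0: np.ndarray
    immigrants: np.ndarray

    @property
    def n_transitions(self) -> int:
        return self.theta.shape[1]

    def annual_params(self, t: int) -> AnnualParams:
        return theta_to_params(self.theta[:, t])

    @classmethod
    def from_draw(cls, draws: PosteriorDraws, chain: int,
                  draw: int) -> "RealizedSeries":
        T = draws.n_years
        nb = draws.nb()[chain, draw]
        tot = nb.sum(axis=0)
        theta = np.zeros((N_PARAMS, T - 1))
        theta[:18] = draws.nat[chain, draw, :, :T - 1]
        psiS = 1.0 / (1.0 + np.exp(-draws.psi_lin[chain, draw]))
        theta[18:24] = psiS[:, None]
        theta[24:28] = nb[:, :-1] / tot[:-1]
        theta[28:32] = draws.immigrants[chain, draw] / tot[:-1]
        return cls(theta=theta, state0=nb[:, 0].copy(),
                   immigrants=draws.immigrants[chain, draw].copy())

    @classmethod
    def from_truth(cls, truth) -> "RealizedSeries":
        T = truth.config.years
        nb = truth.nb
        tot = nb.sum(axis=0)
        theta = np.zeros((N_PARAMS, T - 1))
        for t in range(T - 1):
            par = truth.params[t]
            theta[0:4, t] = par.b.ravel()
            theta[4:8, t] = par.fled.ravel()
            theta[8:10, t] = par.phi_fl
            theta[10:14, t] = par.phi_succ.ravel()
            theta[14:18, t] = par.phi_fail.ravel()
            theta[18:20, t] = par.psi_fl[:, 0]
            theta[20:22, t] = par.psi_succ[:, 0]
            theta[22:24, t] = par.psi_fail[:, 0]
            theta[24:28, t] = nb[:, t] / tot[t]
            theta[28:32, t] = truth.immigrants[:, t] / tot[t]
        return cls(theta=theta, state0=nb[:, 0].astype(float),
                   immigrants=truth.immigrants.astype(float))


def theta_to_params(theta: np.ndarray) -> AnnualParams:
    """Rebuild an :class:`AnnualParams` from one LTRE argument column."""
    psiS = theta[18:24]
    mk = lambda s: np.column_stack([s, 1.0 - s])
    return AnnualParams(
        b=np.clip(theta[0:4], 0, 1).reshape(2, 2),
        fled=np.maximum(theta[4:8], 0.5).reshape(2, 2),
        phi_fl=np.clip(theta[8:10], 0, 1),
        phi_succ=np.clip(theta[10:14], 0, 1).reshape(2, 2),
        phi_fail=np.clip(theta[14:18], 0, 1).reshape(2, 2),
        psi_fl=mk(np.clip(psiS[0:2], 0, 1)),
        psi_succ=mk(np.clip(psiS[2:4], 0, 1)),
        psi_fail=mk(np.clip(psiS[4:6], 0, 1)))


def matrix_from_theta(theta: np.ndarray) -> np.ndarray:
    """Annual projection matrix straight from one LTRE argument column
    (fast path equivalent to ``build_projection_matrix(theta_to_params(.))``)."""
    b = theta[0:4]
    fled = theta[4:8]
    phifl = theta[8:10]
    phis = theta[10:14]
    phif = theta[14:18]
    pflS, psS, pfS = theta[18:20], theta[20:22], theta[22:24]
    A = np.zeros((4, 4))
    for k in range(4):
        a, h = divmod(k, 2)
        i = 2 * a + h
        recr = b[i] * fled[i] * phifl[h]
        A[0, k] = recr * pflS[h]
        A[1, k] = recr * (1.0 - pflS[h])
        sv_s = b[i] * phis[i]
        sv_f = (1.0 - b[i]) * phif[i]
        A[2, k] = sv_s * psS[h] + sv_f * pfS[h]
        A[3, k] = sv_s * (1.0 - psS[h]) + sv_f * (1.0 - pfS[h])
    return A


def lambda_from_theta(theta: np.ndarray) -> float:
    """Realized growth implied by one LTRE argument column."""
    A = matrix_from_theta(theta)
    n = theta[24:28]
    return float(A.sum(axis=0) @ n + theta[28:32].sum())


def transient_sensitivities(theta_ref: np.ndarray,
                            step: float = 1e-6) -> np.ndarray:
    """Central-difference sensitivities d(lambda)/d(theta_i) at a reference
    point (typically the across-year means of the realized values)."""
    s = np.zeros(N_PARAMS)
    for i in range(N_PARAMS):
        up = theta_ref.copy()
        dn = theta_ref.copy()
        up[i] += step
        dn[i] -= step
        s[i] = (lambda_from_theta(up) - lambda_from_theta(dn)) / (2 * step)
    return s


def variance_contributions(theta_series: np.ndarray,
                           sensitivities: np.ndarray | None = None
                           ) -> np.ndarray:
    """Covariance-weighted LTRE contributions for one realized series.

    Returns per-parameter contributions ``sum_j cov(theta_i, theta_j) s_i
    s_j``; their total equals the first-order approximation of the variance
    of the reconstructed lambda series.
    """
    if theta_series.shape[1] < 3:
        raise ValueError("need at least three transition years")
    if sensitivities is None:
        sensitivities = transient_sensitivities(theta_series.mean(axis=1))
    cov = np.cov(theta_series, ddof=1)
    # a parameter that never varies contributes exactly zero; guard against
    # round-off from the mean subtraction inside the covariance
    const = np.ptp(theta_series, axis=1) == 0.0
    cov[const, :] = 0.0
    cov[:, const] = 0.0
    weighted = cov * np.outer(sensitivities, sensitivities)
    return weighted.sum(axis=1)


def yearly_contributions(theta_series: np.ndarray) -> np.ndarray:
    """Year-specific contributions: (theta_{t+1} - theta_t) times the
    sensitivity evaluated at year t.  Shape (N_PARAMS, T-2)."""
    nt = theta_series.shape[1]
    if nt < 2:
        raise ValueError("need at least two transition years")
    out = np.zeros((N_PARAMS, nt - 1))
    for t in range(nt - 1):
        s_t = transient_sensitivities(theta_series[:, t])
        out[:, t] = (theta_series[:, t + 1] - theta_series[:, t]) * s_t
    return out


@dataclass
class ContributionTable:
    """Per-parameter and per-group LTRE contributions with 95% CIs."""

    per_parameter: pd.DataFrame
    per_group: pd.DataFrame
    var_lambda: float

    def normalized_share(self, group: str) -> float:
        return float(self.per_group.loc[group, "share"])


def ltre_decomposition(draws: PosteriorDraws, max_draws: int = 400,
                       seed: int = 0) -> ContributionTable:
    """Full transient LTRE over the posterior.

    Contributions are computed per draw from that draw's realized annual
    values, then summarized; shares are contributions normalized by the
    summed contribution within each draw.  ``var_lambda`` is the posterior
    mean variance of the reconstructed annual growth rates.
    """
    rng = np.random.default_rng(seed)
    C, D = draws.n_chains, draws.n_draws
    total = C * D
    take = min(max_draws, total)
    pick = rng.choice(total, size=take, replace=False)
    contrib = np.zeros((take, N_PARAMS))
    varlam = np.zeros(take)
    for j, flat in enumerate(pick):
        ci, di = divmod(int(flat), D)
        rs = RealizedSeries.from_draw(draws, ci, di)
        contrib[j] = variance_contributions(rs.theta)
        lam = np.array([lambda_from_theta(rs.theta[:, t])
                        for t in range(rs.n_transitions)])
        varlam[j] = lam.var(ddof=1)

    rows = []
    tot = contrib.sum(axis=1)
    for i, name in enumerate(LTRE_PARAM_NAMES):
        rows.append({
            "parameter": name, "group": GROUP_OF[name],
            "contribution": contrib[:, i].mean(),
            "lo": np.quantile(contrib[:, i], 0.025),
            "hi": np.quantile(contrib[:, i], 0.975),
            "share": np.mean(contrib[:, i] / tot)})
    per_param = pd.DataFrame(rows).set_index("parameter")
    grows = []
    for g in GROUP_ORDER:
        mask = np.array([GROUP_OF[n] == g for n in LTRE_PARAM_NAMES])
        gsum = contrib[:, mask].sum(axis=1)
        grows.append({
            "group": g, "contribution": gsum.mean(),
            "lo": np.quantile(gsum, 0.025),
            "hi": np.quantile(gsum, 0.975),
            "share": np.mean(gsum / tot)})
    per_group = pd.DataFrame(grows).set_index("group")
    return ContributionTable(per_parameter=per_param, per_group=per_group,
                             var_lambda=float(varlam.mean()))


def local_demography_share(table: ContributionTable) -> dict:
    """Headline shares: local demography vs apparent immigration, and the
    split of the local-demography part (habitats, structure, fledgling
    recruitment from Short sites)."""
    pg = table.per_group
    local = (pg.loc["short_demography", "contribution"]
             + pg.loc["tall_demography", "contribution"]
             + pg.loc["structure", "contribution"])
    imm = pg.loc["immigration", "contribution"]
    total = local + imm
    pp = table.per_parameter
    recr_S = pp.loc["phi_fl_S", "contribution"]
    return {
        "local_demography": float(local / total),
        "immigration": float(imm / total),
        "short_within_local":
            float(pg.loc["short_demography", "contribution"] / local),
        "structure_within_local":
            float(pg.loc["structure", "contribution"] / local),
        "fledgling_recruitment_S_within_local": float(recr_S / local),
    }
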