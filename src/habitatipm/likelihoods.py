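"""Submodel likelihoods joined by the integrated population model.

Four data streams, one shared parameter set:

* breeding-success trials  -> binomial likelihood in ``b``;
* fledgling counts at successful sites -> shifted-Poisson likelihood in
  ``fled`` (``F - S ~ Poisson(S * (2*fled - 1))``; ``fled`` is the per-sex
  mean so a successful brood always holds at least one fledgling);
* adult mark--resight histories -> multi-event hidden-state likelihood with
  state uncertainty, evaluated by the forward algorithm;
* fledgling mark--resight (one event the year after ringing) -> closed-form
  recruitment likelihood;
* territory counts -> state-space likelihood with latent integer flows
  (Poisson recruitment, multinomial adult survival-and-movement, Poisson
  apparent immigration) and Poisson observation error.

Event codes, adult dialect: 0 not seen; 1 seen in S successful; 2 seen in S
failed; 3 seen in S success unknown; 4-6 the same for T.  Juvenile dialect:
0 not seen; 1 seen breeding in S; 2 seen breeding in T.

Hidden states for the adult model: (age, habitat, success) with success
first, i.e. index ``4*age + 2*habitat + status`` where status 0 = successful
and 1 = failed, plus state 8 = dead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import AnnualParams, N_CLASSES

N_STATES = 9          # 8 live (age x habitat x success) + dead
DEAD = 8
N_EVENTS = 7

ADULT_EVENT_CODES = tuple(range(7))
JUVENILE_EVENT_CODES = (0, 1, 2)


class SchemaError(ValueError):
    """A table does not match its documented schema."""


class EventCodeError(ValueError):
    """An event history contains a code outside its dialect."""


def _check_columns(df: pd.DataFrame, cols: tuple, name: str) -> pd.DataFrame:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{name} is missing columns {sorted(missing)}")
    return df.loc[:, list(cols)].reset_index(drop=True)


@dataclass
class BreedingTable:
    """(year, age, habitat, n_monitored, n_successful) rows."""

    df: pd.DataFrame
    COLUMNS = ("year", "age", "habitat", "n_monitored", "n_successful")

    def __post_init__(self) -> None:
        self.df = _check_columns(self.df, self.COLUMNS, "BreedingTable")
        bad = self.df[(self.df.n_successful < 0)
                      | (self.df.n_successful > self.df.n_monitored)]
        if len(bad):
            raise SchemaError(
                f"BreedingTable rows with successes outside [0, monitored]: "
                f"rows {bad.index.tolist()}")

    @classmethod
    def from_records(cls, rows) -> "BreedingTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))


@dataclass
class FledglingTable:
    """(year, age, habitat, n_known, total_fledglings) rows; counts are
    both-sex totals over the successful broods with known size."""

    df: pd.DataFrame
    COLUMNS = ("year", "age", "habitat", "n_known", "total_fledglings")

    def __post_init__(self) -> None:
        self.df = _check_columns(self.df, self.COLUMNS, "FledglingTable")
        bad = self.df[(self.df.n_known < 0)
                      | (self.df.total_fledglings < self.df.n_known)]
        if len(bad):
            raise SchemaError(
                f"FledglingTable rows with fewer fledglings than broods: "
                f"rows {bad.index.tolist()}")

    @classmethod
    def from_records(cls, rows) -> "FledglingTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))


@dataclass
class CountTable:
    """(year, age, habitat, count) occupied-territory counts."""

    df: pd.DataFrame
    COLUMNS = ("year", "age", "habitat", "count")

    def __post_init__(self) -> None:
        self.df = _check_columns(self.df, self.COLUMNS, "CountTable")
        if (self.df["count"] < 0).any():
            raise SchemaError("CountTable contains negative counts")

    @classmethod
    def from_records(cls, rows) -> "CountTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def to_array(self, n_years: int) -> np.ndarray:
        """(4, n_years) array in the global class order."""
        y = np.zeros((N_CLASSES, n_years))
        for _, r in self.df.iterrows():
            y[2 * int(r.age) + int(r.habitat), int(r.year)] = r["count"]
        return y


@dataclass
class AdultHistories:
    """Adult multi-event histories conditioned on a known first capture.

    ``first_state`` is the live-state index (age, habitat, success known by
    protocol at first capture); ``events[i, t]`` holds the event code for
    year ``t > first_year[i]`` and is ignored otherwise.
    """

    first_year: np.ndarray
    first_state: np.ndarray
    events: np.ndarray
    n_years: int

    def __post_init__(self) -> None:
        self.first_year = np.asarray(self.first_year, dtype=int)
        self.first_state = np.asarray(self.first_state, dtype=int)
        self.events = np.asarray(self.events, dtype=int)
        if self.events.ndim != 2 or self.events.shape[1] != self.n_years:
            raise SchemaError("events must be (n_individuals, n_years)")
        if np.any((self.first_state < 0) | (self.first_state >= DEAD)):
            raise EventCodeError("first_state must be a live state index 0-7")
        bad = np.argwhere((self.events < 0) | (self.events >= N_EVENTS))
        if len(bad):
            i, t = bad[0]
            raise EventCodeError(
                f"invalid adult event code {self.events[i, t]} for "
                f"individual {i}, year {t}")
        if np.any((self.first_year < 0) | (self.first_year >= self.n_years)):
            raise SchemaError("first capture outside the study window")

    def __len__(self) -> int:
        return len(self.first_year)


@dataclass
class JuvenileHistories:
    """One next-year event per ringed fledgling of the modeled sex."""

    natal_habitat: np.ndarray
    birth_year: np.ndarray
    event: np.ndarray
    n_years: int

    def __post_init__(self) -> None:
        self.natal_habitat = np.asarray(self.natal_habitat, dtype=int)
        self.birth_year = np.asarray(self.birth_year, dtype=int)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(~np.isin(self.event, JUVENILE_EVENT_CODES)):
            bad = int(np.argwhere(~np.isin(self.event,
                                           JUVENILE_EVENT_CODES))[0, 0])
            raise EventCodeError(
                f"invalid juvenile event code {self.event[bad]} at row {bad}")
        if np.any((self.birth_year < 0) | (self.birth_year > self.n_years - 2)):
            raise SchemaError("juveniles must be born at least one year "
                              "before the final census")

    def __len__(self) -> int:
        return len(self.event)


@dataclass
class ObservedDataset:
    """The four observed data streams for one study period."""

    breeding: BreedingTable
    fledgling: FledglingTable
    adults: AdultHistories
    juveniles: JuvenileHistories
    counts: CountTable | None

    @property
    def n_years(self) -> int:
        return self.adults.n_years


# ---------------------------------------------------------------------------
# productivity / fecundity submodels
# ---------------------------------------------------------------------------

def breeding_success_loglik(table: BreedingTable, b: np.ndarray) -> float:
    """Binomial log likelihood of the success trials; ``b`` is (2, 2, T)."""
    total = 0.0
    for _, r in table.df.iterrows():
        R, B = int(r.n_monitored), int(r.n_successful)
        if B > R:
            raise ValueError("more successes than monitored sites")
        if R == 0:
            continue
        prob = b[int(r.age), int(r.habitat), int(r.year)]
        if not 0.0 < prob < 1.0:
            if (prob == 0.0 and B == 0) or (prob == 1.0 and B == R):
                continue
            return -np.inf
        total += (gammaln(R + 1) - gammaln(B + 1) - gammaln(R - B + 1)
                  + B * np.log(prob) + (R - B) * np.log1p(-prob))
    return float(total)


def fledgling_loglik(table: FledglingTable, fled: np.ndarray) -> float:
    """Shifted-Poisson log likelihood of total fledgling counts.

    For a class-year with ``S`` successful broods of known size totalling
    ``F`` fledglings, ``F - S ~ Poisson(S * (2*fled - 1))`` where ``fled``
    (shape (2, 2, T)) is the per-sex mean brood size.
    """
    total = 0.0
    for _, r in table.df.iterrows():
        S, F = int(r.n_known), int(r.total_fledglings)
        if F < S:
            raise ValueError("fewer fledglings than successful broods")
        if S == 0:
            continue
        rate = S * (2.0 * fled[int(r.age), int(r.habitat), int(r.year)] - 1.0)
        k = F - S
        if rate <= 0.0:
            if k != 0 or rate < 0.0:
                return -np.inf
            continue
        total += k * np.log(rate) - rate - gammaln(k + 1)
    return float(total)


# ---------------------------------------------------------------------------
# adult multi-event capture--mark--resight submodel
# ---------------------------------------------------------------------------

def build_adult_transition_matrix(params: AnnualParams,
                                  params_next: AnnualParams) -> np.ndarray:
    """Hidden-state transition matrix from year t to year t+1 (9 x 9).

    From live state (a, h, s): survive with the success-matched ``phi``,
    move with the success-matched ``psi``, become Old, and draw next year's
    success with ``b[O, h']`` from ``params_next`` (every survivor is an Old
    breeder the following year).  Death is absorbing.
    """
    M = np.zeros((N_STATES, N_STATES))
    for a in range(2):
        for h in range(2):
            for s in range(2):  # 0 = successful, 1 = failed
                i = 4 * a + 2 * h + s
                phi = (params.phi_succ if s == 0 else params.phi_fail)[a, h]
                psi = (params.psi_succ if s == 0 else params.psi_fail)[h]
                for h2 in range(2):
                    b2 = params_next.b[1, h2]
                    M[i, 4 + 2 * h2 + 0] += phi * psi[h2] * b2
                    M[i, 4 + 2 * h2 + 1] += phi * psi[h2] * (1.0 - b2)
                M[i, DEAD] = 1.0 - phi
    M[DEAD, DEAD] = 1.0
    return M


def build_observation_matrix(p: float, c: float) -> np.ndarray:
    """Event emission matrix (9 states x 7 events).

    A live breeder in habitat h with status s is not seen with ``1 - p``,
    seen with its success recorded with ``p * c``, and seen with unknown
    success with ``p * (1 - c)``.  Dead birds are never seen.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= c <= 1.0):
        raise ValueError("p and c must be probabilities")
    O = np.zeros((N_STATES, N_EVENTS))
    for a in range(2):
        for h in range(2):
            for s in range(2):
                i = 4 * a + 2 * h + s
                O[i, 0] = 1.0 - p
                O[i, 1 + 3 * h + s] = p * c
                O[i, 3 + 3 * h] = p * (1.0 - c)
    O[DEAD, 0] = 1.0
    return O


def adult_transition_stack(params: Sequence[AnnualParams]) -> np.ndarray:
    """(T-1, 9, 9) stack of year-to-year transition matrices."""
    return np.stack([build_adult_transition_matrix(params[t], params[t + 1])
                     for t in range(len(params) - 1)])


def adult_multievent_loglik(histories: AdultHistories,
                            params: Sequence[AnnualParams]) -> float:
    """Forward-algorithm log likelihood of the adult histories.

    Each individual is conditioned on its known first-capture state; birds
    unobserved after release may be alive and present (the hidden dead state
    absorbs the alternative).
    """
    T = histories.n_years
    if len(params) != T:
        raise ValueError("need one AnnualParams per study year")
    trans = adult_transition_stack(params)
    obs = build_observation_matrix(params[0].p, params[0].c)
    total = 0.0
    for i in range(len(histories)):
        alpha = np.zeros(N_STATES)
        alpha[histories.first_state[i]] = 1.0
        ll = 0.0
        for t in range(histories.first_year[i], T - 1):
            alpha = (alpha @ trans[t]) * obs[:, histories.events[i, t + 1]]
            norm = alpha.sum()
            if norm <= 0.0:
                return -np.inf
            ll += np.log(norm)
            alpha /= norm
        total += ll
    return float(total)


def juvenile_recruitment_loglik(histories: JuvenileHistories,
                                phi_fl: np.ndarray, psi_fl: np.ndarray,
                                p: float) -> float:
    """Closed-form log likelihood of the single-event fledgling histories.

    ``phi_fl`` is (2, T-1) by natal habitat and birth year; a fledgling is
    seen breeding in habitat h' with probability
    ``phi_fl[natal, year] * psi_fl[natal, h'] * p`` and otherwise not seen
    (settlement is marginalized: ``P(not seen) = 1 - phi_fl * p``).
    """
    total = 0.0
    for nh, by, ev in zip(histories.natal_habitat, histories.birth_year,
                          histories.event):
        f = phi_fl[nh, by]
        if ev == 0:
            pr = 1.0 - f * p
        else:
            pr = f * psi_fl[nh, ev - 1] * p
        if pr <= 0.0:
            return -np.inf
        total += np.log(pr)
    return float(total)


# ---------------------------------------------------------------------------
# count state-space submodel with apparent immigration
# ---------------------------------------------------------------------------

@dataclass
class CountLatentState:
    """Latent integer demographic flows underlying the count data.

    ``n0``: breeders per class in year 0.  For each transition t -> t+1:
    ``recruits[h, h', t]`` locally produced one-year-olds from natal habitat
    h settling in h'; ``adult_flows[k, h', t]`` survivors from source class
    k moving to habitat h'; ``immigrants[k, t]`` apparent immigrants joining
    class k at year t+1.
    """

    n0: np.ndarray
    recruits: np.ndarray       # (2, 2, T-1)
    adult_flows: np.ndarray    # (4, 2, T-1)
    immigrants: np.ndarray     # (4, T-1)

    def __post_init__(self) -> None:
        for name in ("n0", "recruits", "adult_flows", "immigrants"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative latent counts in {name}")
            setattr(self, name, arr)

    @property
    def n_years(self) -> int:
        return self.immigrants.shape[1] + 1

    def nb_trajectory(self) -> np.ndarray:
        """(4, T) implied breeder counts; year t+1 is assembled from the
        period-t flows (recruits and survivors by destination plus
        immigrants)."""
        T = self.n_years
        nb = np.zeros((N_CLASSES, T))
        nb[:, 0] = self.n0
        for t in range(T - 1):
            for h2 in range(2):
                nb[h2, t + 1] = (self.recruits[:, h2, t].sum()
                                 + self.immigrants[h2, t])
                nb[2 + h2, t + 1] = (self.adult_flows[:, h2, t].sum()
                                     + self.immigrants[2 + h2, t])
        return nb


def _poisson_logpmf(k: float, rate: float) -> float:
    if rate <= 0.0:
        return 0.0 if k == 0 else -np.inf
    return k * np.log(rate) - rate - gammaln(k + 1)


def count_state_space_loglik(counts: CountTable | None,
                             latent: CountLatentState,
                             params: Sequence[AnnualParams],
                             imm_means: np.ndarray) -> float:
    """Log likelihood of the latent demographic process and the counts.

    Process: recruits to each habitat pair ~ Poisson with the projection-
    matrix recruitment rate, survivors per source class ~ multinomial with
    the success-conditional survival-and-movement probabilities, immigrants
    ~ Poisson(max(imm_mean, 0)).  Observation: counts ~ Poisson(latent NB).
    """
    T = latent.n_years
    nb = latent.nb_trajectory()
    total = 0.0
    for t in range(T - 1):
        par = params[t]
        for h in range(2):
            for h2 in range(2):
                rate = sum(nb[2 * a + h, t] * par.b[a, h] * par.fled[a, h]
                           * par.phi_fl[h] * par.psi_fl[h, h2]
                           for a in range(2))
                total += _poisson_logpmf(latent.recruits[h, h2, t], rate)
        for k in range(N_CLASSES):
            a, h = divmod(k, 2)
            q = [par.b[a, h] * par.phi_succ[a, h] * par.psi_succ[h, h2]
                 + (1 - par.b[a, h]) * par.phi_fail[a, h] * par.psi_fail[h, h2]
                 for h2 in range(2)]
            n = nb[k, t]
            x = latent.adult_flows[k, :, t]
            d = n - x.sum()
            if d < 0:
                return -np.inf
            qd = 1.0 - q[0] - q[1]
            terms = gammaln(n + 1) - gammaln(x[0] + 1) - gammaln(x[1] + 1) \
                - gammaln(d + 1)
            for xv, qv in zip([x[0], x[1], d], [q[0], q[1], qd]):
                if qv <= 0.0:
                    if xv != 0:
                        return -np.inf
                else:
                    terms += xv * np.log(qv)
            total += terms
            total += _poisson_logpmf(latent.immigrants[k, t],
                                     max(imm_means[k, t], 0.0))
    if counts is not None:
        y = counts.to_array(T)
        for t in range(T):
            for k in range(N_CLASSES):
                total += _poisson_logpmf(y[k, t], nb[k, t])
    return float(total)


def joint_loglik(dataset: ObservedDataset, params: Sequence[AnnualParams],
                 latent: CountLatentState, imm_means: np.ndarray) -> float:
    """Sum of the submodel log likelihoods under the shared parameter set."""
    T = dataset.n_years
    b = np.stack([p.b for p in params], axis=-1)
    fled = np.stack([p.fled for p in params], axis=-1)
    phi_fl = np.stack([p.phi_fl for p in params[:-1]], axis=-1)
    return (breeding_success_loglik(dataset.breeding, b)
            + fledgling_loglik(dataset.fledgling, fled)
            + adult_multievent_loglik(dataset.adults, params)
            + juvenile_recruitment_loglik(dataset.juveniles, phi_fl,
                                          params[0].psi_fl, params[0].p)
            + count_state_space_loglik(dataset.counts, latent, params,
                                       imm_means))
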