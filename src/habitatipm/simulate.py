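"""Individual-based simulator for a two-habitat, age-structured breeding
population observed through four imperfect data streams.

The generator plays the role of the field study: it simulates every breeder
and fledgling individually (demographic stochasticity), applies year-random
variation to the vital rates on their link scales (logit for probabilities,
log for brood size), lets apparent immigrants join each class as Poisson
arrivals, and then degrades the truth into the four observed tables the
model consumes:

* breeding-success trials per year, age class and habitat,
* fledgling counts at the subset of successful sites with known brood size,
* multi-event mark--resight histories for adults (detection ``p``, state
  certainty ``c``) and a single next-year resighting event for fledglings,
* territory counts with Poisson observation error.

Default parameter values are the point estimates of the study population
the package models (a declining northern wheatear population breeding in
Short- and Tall-vegetation farmland habitats over 24 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import AnnualParams, N_CLASSES, PopulationState
from .likelihoods import (AdultHistories, BreedingTable, CountTable,
                          FledglingTable, JuvenileHistories, ObservedDataset)

logit = lambda x: np.log(x / (1.0 - x))
expit = lambda x: 1.0 / (1.0 + np.exp(-x))


def default_mean_params() -> AnnualParams:
    """Study-like mean vital rates (males; fled is the per-sex brood mean)."""
    return AnnualParams(
        b=[[0.71, 0.60], [0.81, 0.66]],
        fled=[[1.29, 1.16], [1.41, 1.235]],
        phi_fl=[0.09, 0.06],
        phi_succ=[[0.46, 0.40], [0.55, 0.40]],
        phi_fail=[[0.49, 0.37], [0.31, 0.30]],
        psi_fl=[[0.80, 0.20], [0.55, 0.45]],
        psi_succ=[[0.90, 0.10], [0.15, 0.85]],
        psi_fail=[[0.70, 0.30], [0.45, 0.55]],
        omega=[[0.14, 0.09], [0.11, 0.10]],
        p=0.90, c=0.91,
    )


@dataclass
class SimulationConfig:
    """Scenario definition: means, temporal SDs (link scale), sampling effort.

    The default scenario mirrors the study conditions: 24 annual censuses,
    initial breeder counts (18, 14, 36, 20) in class order (Y_S, Y_T, O_S,
    O_T), immigration means implying an apparent-immigration rate around
    0.44 of the population, and temporal SDs chosen so that the realized
    coefficients of temporal variation match the reported ones.
    """

    years: int = 24
    mean_params: AnnualParams = field(default_factory=default_mean_params)
    sd_logit_b: np.ndarray = field(
        default_factory=lambda: np.array([[0.31, 0.30], [0.37, 0.50]]))
    sd_log_fled: np.ndarray = field(
        default_factory=lambda: np.array([[0.05, 0.07], [0.02, 0.04]]))
    sd_logit_phi_fl: np.ndarray = field(
        default_factory=lambda: np.array([0.51, 0.27]))
    sd_logit_phi_succ: np.ndarray = field(
        default_factory=lambda: np.array([[0.24, 0.25], [0.24, 0.27]]))
    sd_logit_phi_fail: np.ndarray = field(
        default_factory=lambda: np.array([[0.55, 0.63], [0.54, 0.46]]))
    #: Poisson mean of immigrant arrivals per class (Y_S, Y_T, O_S, O_T)
    imm_mean: np.ndarray = field(
        default_factory=lambda: np.array([12.3, 7.9, 9.7, 8.8]))
    #: log-scale temporal SD of the immigration means
    sd_log_imm: float = 0.6
    initial_counts: np.ndarray = field(
        default_factory=lambda: np.array([18, 14, 36, 20]))
    #: share of occupied sites whose breeding success is monitored
    monitor_breeding: float = 0.91
    #: share of successful broods whose fledgling count is known
    monitor_fledglings: float = 0.5
    #: share of never-ringed new breeders entering the adult mark-resight set
    adult_marking_fraction: float = 0.5
    #: share of modeled-sex fledglings ringed in the nest
    juvenile_marking_fraction: float = 1.0
    #: bypass Poisson observation error on counts (perfect-observation tests)
    exact_counts: bool = False
    seed: int = 20190205

    def __post_init__(self) -> None:
        if self.years < 3:
            raise ValueError("need at least 3 years")
        for name in ("sd_logit_b", "sd_log_fled", "sd_logit_phi_fl",
                     "sd_logit_phi_succ", "sd_logit_phi_fail", "imm_mean",
                     "initial_counts"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        for name in ("monitor_breeding", "monitor_fledglings",
                     "adult_marking_fraction", "juvenile_marking_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sd_log_imm < 0:
            raise ValueError("sd_log_imm must be non-negative")


@dataclass
class Individual:
    """One breeder's true fate record: class (age, habitat, success) per
    breeding year, from first breeding until death/emigration."""

    first_year: int
    kind: str                      # "initial", "recruit" or "immigrant"
    states: list = field(default_factory=list)  # (age, hab, succ) per year

    def state_in(self, year: int):
        k = year - self.first_year
        if 0 <= k < len(self.states):
            return self.states[k]
        return None


@dataclass
class SimulationTruth:
    """Latent side of a simulated dataset (everything the field crew never sees)."""

    config: SimulationConfig
    params: list                       # AnnualParams per year
    imm_means: np.ndarray              # (4, years-1) realized Poisson means
    states: list                       # PopulationState per year
    recruits_by_origin: np.ndarray     # (2, 2, years-1) natal hab x dest hab
    adult_flows: np.ndarray            # (4, 2, years-1) source class x dest hab
    immigrants: np.ndarray             # (4, years-1) arrivals at year t+1
    successes: np.ndarray              # (4, years) successful breeders
    individuals: list                  # Individual records (breeders)
    brood_sizes: dict                  # (year, age, hab) -> both-sex sizes
    juveniles: dict                    # arrays: natal_h, birth_year, recruited, dest_h
    extinct: bool = False

    @property
    def nb(self) -> np.ndarray:
        """(4, years) true breeder counts."""
        return np.stack([s.nb for s in self.states], axis=1)


@dataclass
class SimulatedDataset:
    truth: SimulationTruth
    observed: ObservedDataset


def draw_year_effects(config: SimulationConfig,
                      rng: np.random.Generator | None = None):
    """Realize per-year vital rates: link-scale mean + Normal(0, SD) deviate.

    Habitat transitions, ``p`` and ``c`` are constant across years.  Returns
    a list of :class:`AnnualParams` (one per year) and the realized
    immigration means, shape ``(4, years - 1)`` (arrivals at years 1..T-1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.mean_params
    T = config.years

    def logit_series(mean, sd, shape):
        z = rng.normal(size=(T,) + shape)
        with np.errstate(divide="ignore"):  # boundary means stay at 0 or 1
            return expit(logit(np.asarray(mean)) + np.asarray(sd) * z)

    b = logit_series(m.b, config.sd_logit_b, (2, 2))
    fled = np.exp(np.log(m.fled) + config.sd_log_fled
                  * rng.normal(size=(T, 2, 2)))
    fled = np.maximum(fled, 0.5)
    phi_fl = logit_series(m.phi_fl, config.sd_logit_phi_fl, (2,))
    phi_succ = logit_series(m.phi_succ, config.sd_logit_phi_succ, (2, 2))
    phi_fail = logit_series(m.phi_fail, config.sd_logit_phi_fail, (2, 2))
    imm = np.exp(np.log(np.maximum(config.imm_mean, 1e-12))[:, None]
                 + config.sd_log_imm * rng.normal(size=(4, T - 1)))
    imm[config.imm_mean == 0] = 0.0

    n0 = float(config.initial_counts.sum())
    params = []
    for t in range(T):
        omega = (imm[:, min(t, T - 2)] / max(n0, 1.0)).reshape(2, 2)
        params.append(AnnualParams(
            b=b[t], fled=fled[t], phi_fl=phi_fl[t], phi_succ=phi_succ[t],
            phi_fail=phi_fail[t], psi_fl=m.psi_fl, psi_succ=m.psi_succ,
            psi_fail=m.psi_fail, omega=omega, p=m.p, c=m.c))
    return params, imm


def simulate_population(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        params: list | None = None,
                        imm_means: np.ndarray | None = None) -> SimulationTruth:
    """Run the individual-based population process and record every fate.

    Each breeder of class (a, h) succeeds with ``b[a,h]``; each successful
    brood fledges ``1 + Poisson(2*fled - 1)`` young in total, each of which
    is of the modeled sex with probability 1/2; each modeled-sex fledgling
    recruits with ``phi_fl[natal]`` and settles via ``psi_fl``; each adult
    survives with the success-matched ``phi`` and moves via the matching
    ``psi``; survivors age Y -> O; immigrants join each class as Poisson
    arrivals.  Extinction is allowed and flagged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if params is None or imm_means is None:
        params, imm_means = draw_year_effects(config, rng)
    T = config.years

    individuals: list[Individual] = []
    live: list[Individual] = []
    for k in range(N_CLASSES):
        a, h = divmod(k, 2)
        for _ in range(int(config.initial_counts[k])):
            ind = Individual(first_year=0, kind="initial", states=[(a, h, -1)])
            individuals.append(ind)
            live.append(ind)

    states = [PopulationState(year=0, nb=config.initial_counts.astype(float))]
    recruits_by_origin = np.zeros((2, 2, T - 1))
    adult_flows = np.zeros((N_CLASSES, 2, T - 1))
    immigrants = np.zeros((N_CLASSES, T - 1))
    successes = np.zeros((N_CLASSES, T))
    brood_sizes: dict = {}
    juv_natal, juv_birth, juv_recruited, juv_dest = [], [], [], []
    extinct = False

    for t in range(T):
        par = params[t]
        next_live: list[Individual] = []
        # breeding season of year t: success and broods
        for ind in live:
            a, h, _ = ind.states[-1]
            succ = rng.random() < par.b[a, h]
            ind.states[-1] = (a, h, int(succ))
            if succ:
                successes[2 * a + h, t] += 1
                size = 1 + rng.poisson(max(2.0 * par.fled[a, h] - 1.0, 0.0))
                brood_sizes.setdefault((t, a, h), []).append(int(size))
                if t < T - 1:
                    n_modeled = rng.binomial(size, 0.5)
                    for _ in range(int(n_modeled)):
                        juv_natal.append(h)
                        juv_birth.append(t)
                        if rng.random() < par.phi_fl[h]:
                            dest = int(rng.random() < par.psi_fl[h, 1])
                            juv_recruited.append(True)
                            juv_dest.append(dest)
                            rec = Individual(first_year=t + 1, kind="recruit",
                                             states=[(0, dest, -1)])
                            individuals.append(rec)
                            next_live.append(rec)
                            recruits_by_origin[h, dest, t] += 1
                        else:
                            juv_recruited.append(False)
                            juv_dest.append(-1)
        if t == T - 1:
            break
        # adult survival and movement into year t+1
        for ind in live:
            a, h, s = ind.states[-1]
            phi = par.phi_succ[a, h] if s == 1 else par.phi_fail[a, h]
            psi = par.psi_succ[h] if s == 1 else par.psi_fail[h]
            if rng.random() < phi:
                dest = int(rng.random() < psi[1])
                ind.states.append((1, dest, -1))
                next_live.append(ind)
                adult_flows[2 * a + h, dest, t] += 1
        # immigration into year t+1
        for k in range(N_CLASSES):
            a, h = divmod(k, 2)
            n_im = rng.poisson(max(imm_means[k, t], 0.0))
            immigrants[k, t] = n_im
            for _ in range(int(n_im)):
                ind = Individual(first_year=t + 1, kind="immigrant",
                                 states=[(a, h, -1)])
                individuals.append(ind)
                next_live.append(ind)
        live = next_live
        nb = np.zeros(N_CLASSES)
        for ind in live:
            a, h, _ = ind.states[-1]
            nb[2 * a + h] += 1
        if nb.sum() == 0:
            extinct = True
        states.append(PopulationState(year=t + 1, nb=nb, im=immigrants[:, t]))

    return SimulationTruth(
        config=config, params=params, imm_means=imm_means, states=states,
        recruits_by_origin=recruits_by_origin, adult_flows=adult_flows,
        immigrants=immigrants, successes=successes, individuals=individuals,
        brood_sizes=brood_sizes,
        juveniles=dict(natal_h=np.array(juv_natal, dtype=int),
                       birth_year=np.array(juv_birth, dtype=int),
                       recruited=np.array(juv_recruited, dtype=bool),
                       dest_h=np.array(juv_dest, dtype=int)),
        extinct=extinct)


def observe_dataset(truth: SimulationTruth,
                    config: SimulationConfig | None = None,
                    rng: np.random.Generator | None = None) -> ObservedDataset:
    """Degrade the truth into the four observed data streams."""
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.default_rng(config.seed)
                                    .integers(2 ** 31))
    T = config.years
    nb = truth.nb

    # breeding-success trials: monitored sites per class-year
    rows_b = []
    for t in range(T):
        for k in range(N_CLASSES):
            a, h = divmod(k, 2)
            n, s = int(nb[k, t]), int(truth.successes[k, t])
            R = rng.binomial(n, config.monitor_breeding) if n else 0
            B = rng.hypergeometric(s, n - s, R) if R else 0
            rows_b.append((t, a, h, int(R), int(B)))
    breeding = BreedingTable.from_records(rows_b)

    # fledgling counts at the subset of successful broods with known size
    rows_f = []
    for t in range(T):
        for k in range(N_CLASSES):
            a, h = divmod(k, 2)
            sizes = truth.brood_sizes.get((t, a, h), [])
            known = [sz for sz in sizes
                     if rng.random() < config.monitor_fledglings]
            rows_f.append((t, a, h, len(known), int(sum(known))))
    fledgling = FledglingTable.from_records(rows_f)

    # adult multi-event histories (birds first captured as adult breeders)
    first_year, first_state, events = [], [], []
    p, c = config.mean_params.p, config.mean_params.c
    for ind in truth.individuals:
        if ind.kind == "recruit" and config.juvenile_marking_fraction >= 1.0:
            continue  # ringed as nestling; never first-captured as an adult
        if rng.random() >= config.adult_marking_fraction:
            continue
        fy = None
        ev = np.zeros(T, dtype=int)
        for j, (a, h, s) in enumerate(ind.states):
            year = ind.first_year + j
            detected = rng.random() < p
            known = rng.random() < c
            if fy is None:
                # first capture requires a detection with certain state
                if detected and known and s >= 0:
                    fy = year
                    first_state.append(4 * a + 2 * h + (1 - s))
            elif detected:
                ev[year] = (1 + 3 * h + (1 - s)) if known else (3 + 3 * h)
        if fy is not None and fy < T - 1:
            first_year.append(fy)
            events.append(ev)
        elif fy is not None:
            first_state.pop()
    adults = AdultHistories(
        first_year=np.array(first_year, dtype=int),
        first_state=np.array(first_state, dtype=int),
        events=(np.stack(events) if events
                else np.zeros((0, T), dtype=int)),
        n_years=T)

    # juvenile single-event histories
    juv = truth.juveniles
    marked = rng.random(juv["natal_h"].size) < config.juvenile_marking_fraction
    ev = np.zeros(juv["natal_h"].size, dtype=int)
    seen = juv["recruited"] & (rng.random(juv["natal_h"].size) < p)
    ev[seen] = 1 + juv["dest_h"][seen]
    juveniles = JuvenileHistories(
        natal_habitat=juv["natal_h"][marked],
        birth_year=juv["birth_year"][marked],
        event=ev[marked], n_years=T)

    # territory counts with Poisson observation error
    rows_c = []
    for t in range(T):
        for k in range(N_CLASSES):
            a, h = divmod(k, 2)
            y = int(nb[k, t]) if config.exact_counts else int(
                rng.poisson(nb[k, t]))
            rows_c.append((t, a, h, y))
    counts = CountTable.from_records(rows_c)

    return ObservedDataset(breeding=breeding, fledgling=fledgling,
                           adults=adults, juveniles=juveniles, counts=counts)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full generator: year effects -> population truth -> observed tables.

    A single :class:`numpy.random.Generator` seeded with ``config.seed``
    drives every draw, so identical configs give identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    params, imm = draw_year_effects(config, rng)
    truth = simulate_population(config, rng, params, imm)
    observed = observe_dataset(truth, config, rng)
    return SimulatedDataset(truth=truth, observed=observed)


def assign_unknown_sexes(total_marked: int, resighted_males: int,
                         resighted_females: int,
                         seed: int | None = None) -> tuple[int, int]:
    """Partition never-resighted nestlings so the overall sex ratio is even.

    Returns the numbers of unresighted birds assigned male and female.  The
    totals are deterministic -- males are topped up to ``total // 2`` and
    females to ``total - total // 2`` (the odd bird goes to the females) --
    while the identity of which bird receives which sex is a uniformly
    random labelling under ``seed``.
    """
    if resighted_males < 0 or resighted_females < 0 or total_marked < 0:
        raise ValueError("counts must be non-negative")
    if resighted_males + resighted_females > total_marked:
        raise ValueError("more resighted birds than marked birds")
    target_males = total_marked // 2
    target_females = total_marked - target_males
    assigned_males = target_males - resighted_males
    assigned_females = target_females - resighted_females
    if assigned_males < 0 or assigned_females < 0:
        raise ValueError("resighted birds of one sex exceed the even-ratio "
                         "target; assignment infeasible")
    # the labelling itself (who gets which sex) is random but unreturned
    # here; callers needing identities can permute indices with this seed
    np.random.default_rng(seed).permutation(assigned_males + assigned_females)
    return int(assigned_males), int(assigned_females)
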