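"""Demographic state, projection matrix, growth rates and habitat productivity.

The population is structured by age class (``Y`` = one-year-old breeders,
``O`` = older breeders) and breeding habitat (``S`` = short ground vegetation,
``T`` = tall ground vegetation).  The global class order is

    (Y_S, Y_T, O_S, O_T)

and every module in the package indexes the four classes this way: class
``k`` has age ``k // 2`` (0 = Y, 1 = O) and habitat ``k % 2`` (0 = S, 1 = T).

Vital rates for one breeding season are collected in :class:`AnnualParams`.
Survival and habitat transitions of breeders are conditional on breeding
success in the current season, so breeding success ``b`` enters both the
fecundity and the survival pathways of the annual projection matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

AGES = ("Y", "O")
HABITATS = ("S", "T")
#: global class order; every 4-vector in the package follows it
CLASS_LABELS = ("Y_S", "Y_T", "O_S", "O_T")
N_CLASSES = 4


def class_index(age: str, habitat: str) -> int:
    """Index of an (age, habitat) class in the global class order."""
    return 2 * AGES.index(age) + HABITATS.index(habitat)


def _as_prob(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {arr!r}")
    return arr


@dataclass
class AnnualParams:
    """All vital rates and structure parameters for one breeding season.

    Arrays indexed ``[age, habitat]`` with age 0 = Y, 1 = O and habitat
    0 = S, 1 = T; transition matrices indexed ``[origin, destination]``.

    Parameters
    ----------
    b
        Breeding success probability per class.
    fled
        Mean number of modeled-sex fledglings per successful brood (half the
        total brood mean under an even sex ratio); must be >= 0.5.
    phi_fl
        Fledgling-to-Young apparent recruitment probability by natal habitat.
    phi_succ, phi_fail
        Adult apparent survival probability given breeding success / failure.
    psi_fl
        Natal-to-breeding habitat transition probabilities (rows sum to 1).
    psi_succ, psi_fail
        Between-year habitat transitions of adults given success / failure.
    omega
        Apparent-immigration rate per class, relative to total population.
    p
        Resighting probability of a breeder.
    c
        State certainty: probability that a resighted breeder's breeding
        success is recorded rather than coded unknown.
    """

    b: np.ndarray
    fled: np.ndarray
    phi_fl: np.ndarray
    phi_succ: np.ndarray
    phi_fail: np.ndarray
    psi_fl: np.ndarray
    psi_succ: np.ndarray
    psi_fail: np.ndarray
    omega: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    p: float = 1.0
    c: float = 1.0

    def __post_init__(self) -> None:
        self.b = _as_prob(self.b, "b").reshape(2, 2)
        self.fled = np.asarray(self.fled, dtype=float).reshape(2, 2)
        if np.any(self.fled < 0.5):
            raise ValueError("fled must be >= 0.5 (a successful brood has at "
                             "least one fledgling in total)")
        self.phi_fl = _as_prob(self.phi_fl, "phi_fl").reshape(2)
        self.phi_succ = _as_prob(self.phi_succ, "phi_succ").reshape(2, 2)
        self.phi_fail = _as_prob(self.phi_fail, "phi_fail").reshape(2, 2)
        for name in ("psi_fl", "psi_succ", "psi_fail"):
            m = _as_prob(getattr(self, name), name).reshape(2, 2)
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError(f"{name} rows must sum to 1, got {m!r}")
            setattr(self, name, m)
        self.omega = np.asarray(self.omega, dtype=float).reshape(2, 2)
        if np.any(self.omega < 0.0):
            raise ValueError("omega must be non-negative")
        self.p = float(_as_prob(self.p, "p"))
        self.c = float(_as_prob(self.c, "c"))

    # -- flat serialization -------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        """Flatten to the canonical key set, e.g. ``b_Y_S`` or ``psi_succ_S_T``."""
        out: dict[str, float] = {}
        for ia, a in enumerate(AGES):
            for ih, h in enumerate(HABITATS):
                out[f"b_{a}_{h}"] = float(self.b[ia, ih])
                out[f"fled_{a}_{h}"] = float(self.fled[ia, ih])
                out[f"phi_succ_{a}_{h}"] = float(self.phi_succ[ia, ih])
                out[f"phi_fail_{a}_{h}"] = float(self.phi_fail[ia, ih])
                out[f"omega_{a}_{h}"] = float(self.omega[ia, ih])
        for ih, h in enumerate(HABITATS):
            out[f"phi_fl_{h}"] = float(self.phi_fl[ih])
            for ij, h2 in enumerate(HABITATS):
                out[f"psi_fl_{h}_{h2}"] = float(self.psi_fl[ih, ij])
                out[f"psi_succ_{h}_{h2}"] = float(self.psi_succ[ih, ij])
                out[f"psi_fail_{h}_{h2}"] = float(self.psi_fail[ih, ij])
        out["p"] = self.p
        out["c"] = self.c
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "AnnualParams":
        def grid(prefix: str) -> np.ndarray:
            return np.array([[d[f"{prefix}_{a}_{h}"] for h in HABITATS]
                             for a in AGES])

        def trans(prefix: str) -> np.ndarray:
            return np.array([[d[f"{prefix}_{h}_{h2}"] for h2 in HABITATS]
                             for h in HABITATS])

        return cls(
            b=grid("b"), fled=grid("fled"),
            phi_fl=np.array([d[f"phi_fl_{h}"] for h in HABITATS]),
            phi_succ=grid("phi_succ"), phi_fail=grid("phi_fail"),
            psi_fl=trans("psi_fl"), psi_succ=trans("psi_succ"),
            psi_fail=trans("psi_fail"),
            omega=grid("omega") if "omega_Y_S" in d else np.zeros((2, 2)),
            p=d.get("p", 1.0), c=d.get("c", 1.0),
        )

    def copy(self) -> "AnnualParams":
        return replace(
            self, b=self.b.copy(), fled=self.fled.copy(),
            phi_fl=self.phi_fl.copy(), phi_succ=self.phi_succ.copy(),
            phi_fail=self.phi_fail.copy(), psi_fl=self.psi_fl.copy(),
            psi_succ=self.psi_succ.copy(), psi_fail=self.psi_fail.copy(),
            omega=self.omega.copy(),
        )


@dataclass
class PopulationState:
    """Breeder counts per class for one year plus that year's immigrants.

    ``nb`` and ``im`` follow the global class order (Y_S, Y_T, O_S, O_T);
    ``im`` holds the apparent immigrants that joined the population at
    this year's census.
    """

    year: int
    nb: np.ndarray
    im: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))

    def __post_init__(self) -> None:
        self.nb = np.asarray(self.nb, dtype=float).reshape(N_CLASSES)
        self.im = np.asarray(self.im, dtype=float).reshape(N_CLASSES)
        if np.any(self.nb < 0) or np.any(self.im < 0):
            raise ValueError("population counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.nb.sum())

    def __getattr__(self, name: str):
        # nb_Y_S-style accessors for the eight count fields
        for prefix, arr_name in (("nb_", "nb"), ("im_", "im")):
            if name.startswith(prefix):
                label = name[len(prefix):]
                if label in CLASS_LABELS:
                    arr = object.__getattribute__(self, arr_name)
                    return float(arr[CLASS_LABELS.index(label)])
        raise AttributeError(name)


@dataclass
class GrowthSeries:
    """Realized annual growth rates lambda_t = N_{t+1} / N_t."""

    lambda_t: np.ndarray
    geometric_mean: float

    @classmethod
    def from_totals(cls, totals: Sequence[float]) -> "GrowthSeries":
        totals = np.asarray(totals, dtype=float)
        if totals.size < 2:
            raise ValueError("need at least two years to compute growth")
        if np.any(totals <= 0):
            raise ValueError("growth is undefined for zero total population")
        lam = totals[1:] / totals[:-1]
        return cls(lambda_t=lam, geometric_mean=float(np.exp(np.mean(np.log(lam)))))


def build_projection_matrix(params: AnnualParams) -> np.ndarray:
    """Annual 4x4 projection matrix in the global class order.

    Recruitment rows (to Y_S, Y_T): a breeder of class (a, h) contributes
    ``b[a,h] * fled[a,h] * phi_fl[h] * psi_fl[h, h']`` one-year-old breeders
    to habitat h'.  Adult rows (to O_S, O_T): the breeder itself survives and
    moves conditionally on its breeding success,
    ``b * phi_succ * psi_succ[h, h'] + (1 - b) * phi_fail * psi_fail[h, h']``.
    """
    A = np.zeros((N_CLASSES, N_CLASSES))
    for k in range(N_CLASSES):
        a, h = divmod(k, 2)
        for h2 in range(2):
            A[h2, k] = (params.b[a, h] * params.fled[a, h]
                        * params.phi_fl[h] * params.psi_fl[h, h2])
            A[2 + h2, k] = (
                params.b[a, h] * params.phi_succ[a, h] * params.psi_succ[h, h2]
                + (1.0 - params.b[a, h]) * params.phi_fail[a, h]
                * params.psi_fail[h, h2])
    return A


def project(state: PopulationState, matrix: np.ndarray,
            immigrants: Iterable[float]) -> PopulationState:
    """Expected next-year state ``A @ nb + im`` (deterministic recursion)."""
    im = np.asarray(list(immigrants), dtype=float).reshape(N_CLASSES)
    if np.any(im < 0):
        raise ValueError("immigrant numbers must be non-negative")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (N_CLASSES, N_CLASSES):
        raise ValueError("projection matrix must be 4x4")
    nb_next = matrix @ state.nb + im
    return PopulationState(year=state.year + 1, nb=nb_next, im=im)


def realized_growth(series: Sequence[PopulationState]) -> GrowthSeries:
    """Annual growth rates and their geometric mean from a state trajectory."""
    return GrowthSeries.from_totals([s.total for s in series])


def habitat_productivity(recruits_from_h: float, surviving_adults_from_h: float,
                         adults_in_h: float) -> float:
    """Habitat productivity: (first-year recruits originating from the habitat
    plus apparently surviving adults from the habitat) per breeder there."""
    if adults_in_h <= 0:
        raise ValueError("productivity undefined with no breeders in habitat")
    if recruits_from_h < 0 or surviving_adults_from_h < 0:
        raise ValueError("counts must be non-negative")
    return (recruits_from_h + surviving_adults_from_h) / adults_in_h


def class_proportions(state: PopulationState) -> np.ndarray:
    """Proportion of each age-by-habitat class among occupied sites."""
    total = state.total
    if total <= 0:
        raise ValueError("class proportions undefined for empty population")
    return state.nb / total
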