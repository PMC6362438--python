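"""CSV readers/writers, run manifests and draw persistence.

CSV is the canonical interchange format.  Years are stored as 0-based
indices internally; a ``year0`` entry in the dataset metadata maps them to
calendar years for presentation.  Schemas:

``breeding.csv``
    year, age, habitat, n_monitored, n_successful
``fledglings.csv``
    year, age, habitat, n_known, total_fledglings
``adult_histories.csv``
    id, first_year, age, habitat, success, history -- ``history`` is the
    per-year event-code string (adult dialect, one digit per study year;
    positions at or before first_year are 0)
``juvenile_histories.csv``
    id, natal_habitat, birth_year, event (juvenile dialect)
``counts.csv``
    year, age, habitat, count

``age`` is 0 = Young, 1 = Old; ``habitat`` 0 = Short, 1 = Tall.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import AnnualParams
from .fit import PosteriorDraws
from .likelihoods import (AdultHistories, BreedingTable, CountTable,
                          EventCodeError, FledglingTable, JuvenileHistories,
                          ObservedDataset, SchemaError)
from .simulate import SimulationConfig


class YearRangeError(ValueError):
    """Tables disagree about the study's year range."""


FILES = ("breeding.csv", "fledglings.csv", "adult_histories.csv",
         "juvenile_histories.csv", "counts.csv")


def write_dataset(dataset: ObservedDataset, outdir) -> list:
    """Write the five observed tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    dataset.breeding.df.to_csv(outdir / "breeding.csv", index=False)
    dataset.fledgling.df.to_csv(outdir / "fledglings.csv", index=False)
    ad = dataset.adults
    rows = []
    for i in range(len(ad)):
        a, rem = divmod(int(ad.first_state[i]), 4)
        h, s = divmod(rem, 2)
        rows.append({
            "id": i, "first_year": int(ad.first_year[i]), "age": a,
            "habitat": h, "success": 1 - s,
            "history": "".join(str(e) for e in ad.events[i])})
    pd.DataFrame(rows, columns=["id", "first_year", "age", "habitat",
                                "success", "history"]).to_csv(
        outdir / "adult_histories.csv", index=False)
    jv = dataset.juveniles
    pd.DataFrame({
        "id": np.arange(len(jv)), "natal_habitat": jv.natal_habitat,
        "birth_year": jv.birth_year, "event": jv.event}).to_csv(
        outdir / "juvenile_histories.csv", index=False)
    if dataset.counts is not None:
        dataset.counts.df.to_csv(outdir / "counts.csv", index=False)
    for f in FILES:
        if (outdir / f).exists():
            paths.append(outdir / f)
    return paths


def read_dataset(indir, require_counts: bool = True) -> ObservedDataset:
    """Read and cross-validate the observed tables from a directory.

    Raises :class:`SchemaError` for malformed tables,
    :class:`EventCodeError` for out-of-dialect codes (naming the row) and
    :class:`YearRangeError` when tables disagree on the year range.
    """
    indir = Path(indir)
    for f in ("breeding.csv", "fledglings.csv", "adult_histories.csv",
              "juvenile_histories.csv"):
        if not (indir / f).exists():
            raise FileNotFoundError(f"missing input table {indir / f}")
    breeding = BreedingTable(pd.read_csv(indir / "breeding.csv"))
    fledgling = FledglingTable(pd.read_csv(indir / "fledglings.csv"))
    T = int(breeding.df.year.max()) + 1
    tf = int(fledgling.df.year.max()) + 1
    counts = None
    if (indir / "counts.csv").exists():
        counts = CountTable(pd.read_csv(indir / "counts.csv"))
        tc = int(counts.df.year.max()) + 1
        if tc != T:
            raise YearRangeError(
                f"counts.csv spans {tc} years but breeding.csv spans {T}")
    elif require_counts:
        raise FileNotFoundError(f"missing input table {indir / 'counts.csv'}")
    if tf != T:
        raise YearRangeError(
            f"fledglings.csv spans {tf} years but breeding.csv spans {T}")

    adf = pd.read_csv(indir / "adult_histories.csv",
                      dtype={"history": str})
    for col in ("first_year", "age", "habitat", "success", "history"):
        if col not in adf.columns:
            raise SchemaError(f"adult_histories.csv missing column {col}")
    events = np.zeros((len(adf), T), dtype=int)
    for i, (_, r) in enumerate(adf.iterrows()):
        hist = str(r.history)
        if len(hist) != T:
            raise SchemaError(
                f"adult_histories.csv row {i}: history length {len(hist)} "
                f"!= {T} study years")
        for t, ch in enumerate(hist):
            if ch not in "0123456":
                raise EventCodeError(
                    f"adult_histories.csv row {i}: invalid adult event "
                    f"code {ch!r} at year {t}")
            events[i, t] = int(ch)
    first_state = (4 * adf.age.to_numpy() + 2 * adf.habitat.to_numpy()
                   + (1 - adf.success.to_numpy()))
    adults = AdultHistories(first_year=adf.first_year.to_numpy(),
                            first_state=first_state, events=events,
                            n_years=T)

    jdf = pd.read_csv(indir / "juvenile_histories.csv")
    for col in ("natal_habitat", "birth_year", "event"):
        if col not in jdf.columns:
            raise SchemaError(f"juvenile_histories.csv missing column {col}")
    bad = jdf[~jdf.event.isin([0, 1, 2])]
    if len(bad):
        raise EventCodeError(
            f"juvenile_histories.csv row {bad.index[0]}: invalid juvenile "
            f"event code {bad.event.iloc[0]}")
    juveniles = JuvenileHistories(natal_habitat=jdf.natal_habitat.to_numpy(),
                                  birth_year=jdf.birth_year.to_numpy(),
                                  event=jdf.event.to_numpy(), n_years=T)
    return ObservedDataset(breeding=breeding, fledgling=fledgling,
                           adults=adults, juveniles=juveniles, counts=counts)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, AnnualParams):
            out[f.name] = v.to_dict()
        elif isinstance(v, np.ndarray):
            out[f.name] = v.tolist()
        else:
            out[f.name] = v
    return out


def config_from_dict(d: dict) -> SimulationConfig:
    kwargs = dict(d)
    if "mean_params" in kwargs and isinstance(kwargs["mean_params"], dict):
        kwargs["mean_params"] = AnnualParams.from_dict(kwargs["mean_params"])
    return SimulationConfig(**kwargs)


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config)))


def load_config(path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def params_to_frame(params: AnnualParams) -> pd.DataFrame:
    d = params.to_dict()
    return pd.DataFrame({"key": list(d), "value": list(d.values())})


# ---------------------------------------------------------------------------
# posterior draw persistence
# ---------------------------------------------------------------------------

def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist posterior draws as a compressed array bundle."""
    np.savez_compressed(
        path, nat=draws.nat, mu=draws.mu, sigma=draws.sigma,
        psi_lin=draws.psi_lin, pc=draws.pc, imm_mean=draws.imm_mean,
        n0=draws.n0, recruits=draws.recruits, adult_flows=draws.adult_flows,
        immigrants=draws.immigrants, loglik=draws.loglik,
        n_years=np.array([draws.n_years]), seed=np.array([draws.seed]))


def load_draws(path) -> PosteriorDraws:
    z = np.load(path)
    return PosteriorDraws(
        nat=z["nat"], mu=z["mu"], sigma=z["sigma"], psi_lin=z["psi_lin"],
        pc=z["pc"], imm_mean=z["imm_mean"], n0=z["n0"],
        recruits=z["recruits"], adult_flows=z["adult_flows"],
        immigrants=z["immigrants"], loglik=z["loglik"],
        n_years=int(z["n_years"][0]), seed=int(z["seed"][0]))


def draws_to_frame(draws: PosteriorDraws, every: int = 10) -> pd.DataFrame:
    """Long-format (chain, draw, parameter, value) table of the annual
    rates and hyperparameters, thinned by ``every`` for portability."""
    from .fit import FAMILY_NAMES, PSI_NAMES
    rows = []
    for ci in range(draws.n_chains):
        for di in range(0, draws.n_draws, every):
            for f, name in enumerate(FAMILY_NAMES):
                ny = draws.n_years if f < 8 else draws.n_years - 1
                for t in range(ny):
                    rows.append((ci, di, f"{name}[{t}]",
                                 draws.nat[ci, di, f, t]))
                rows.append((ci, di, f"mu_{name}", draws.mu[ci, di, f]))
                rows.append((ci, di, f"sigma_{name}",
                             draws.sigma[ci, di, f]))
            for j, name in enumerate(PSI_NAMES):
                rows.append((ci, di, name,
                             1 / (1 + np.exp(-draws.psi_lin[ci, di, j]))))
            rows.append((ci, di, "p", draws.pc[ci, di, 0]))
            rows.append((ci, di, "c", draws.pc[ci, di, 1]))
    return pd.DataFrame(rows, columns=["chain", "draw", "parameter",
                                       "value"])


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record written by every CLI run."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    convergence_flags: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def add_inputs(self, paths) -> None:
        for p in paths:
            p = Path(p)
            self.input_digests[p.name] = hashlib.sha256(
                p.read_bytes()).hexdigest()

    def finish(self, path) -> None:
        self.finished = time.time()
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=2, default=str))
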