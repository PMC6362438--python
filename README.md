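# habitatipm

A habitat- and age-structured Bayesian **integrated population model**
(IPM) for territorial bird populations breeding in two contrasting land-use
habitats, with **apparent immigration** estimated as the residual of the
count process, a **transient LTRE** variance decomposition of realized
growth, and **real-time transient elasticities** for scenario analysis.

The package is written for population ecologists asking how much each
habitat — here "Short" (permanently short ground vegetation, e.g. grazed
pasture) versus "Tall" (growing field layer, e.g. crop fields) — and each
demographic pathway contributed to past variation in population growth,
and where management leverage lies.  It ships a full individual-based
synthetic-data generator so the entire pipeline is testable end to end
without any field data.

## Model

Breeders belong to four classes in the fixed order (Y_S, Y_T, O_S, O_T):
Young (one-year-old) or Old crossed with Short or Tall habitat.  The
population process is

```
NB(t+1) = A_t · NB(t) + Im(t+1)
```

with the annual projection matrix `A_t` built from breeding success
`b[a,h]`, modeled-sex brood size `fled[a,h]`, first-year apparent
recruitment `phi_fl[h]` with natal-to-breeding settlement `psi_fl`, and
success-conditional adult apparent survival and movement
(`b·phi_succ·psi_succ + (1−b)·phi_fail·psi_fail`).  `Im` are the apparent
immigrants per class — the inflow local demography cannot explain.

Four data streams share these parameters in one posterior: binomial
breeding-success trials, shifted-Poisson fledgling counts
(`F−S ~ Poisson(S(2·fled−1))`), adult **multi-event** mark–resight
histories with state uncertainty (detection `p`, state certainty `c`;
hidden states marginalized exactly by the forward algorithm), a one-event
juvenile recruitment layer, and Poisson-observed territory counts over a
latent integer flow process.  Year-random effects act on logit/log scales;
fitting is by an adaptive Metropolis-within-Gibbs sampler (numba) with
split-R̂ convergence diagnostics and posterior predictive checks.  See
`docs/methods.md` for the full account.

## Worked example

```python
import habitatipm as hp
from habitatipm.fit import fit_ipm, summarize_posterior
from habitatipm.ltre import ltre_decomposition, local_demography_share

cfg = hp.SimulationConfig()          # the default 24-year study
ds = hp.simulate_dataset(cfg)
draws = fit_ipm(ds.observed, seed=1) # 3 chains, 3000 kept after 1000 burn-in
summ = summarize_posterior(draws)
print(summ.loc[["b_O_S", "f_O_S", "phi_fl_S", "omega_total",
                "lambda_geometric_mean", "productivity_S",
                "productivity_T"], ["mean", "lo", "hi", "cv"]].round(2))
table = ltre_decomposition(draws, seed=1)
shares = local_demography_share(table)
print(f"local demography: {100*shares['local_demography']:.0f}%  "
      f"immigration: {100*shares['immigration']:.0f}%")
```

prints (about half a minute):

```
                       mean    lo    hi    cv
parameter
b_O_S                  0.80  0.77  0.82  0.04
f_O_S                  2.87  2.73  3.02  0.04
phi_fl_S               0.13  0.11  0.15  0.47
omega_total            0.45  0.41  0.49   NaN
lambda_geometric_mean  1.01  1.00  1.02   NaN
productivity_S         0.64  0.59  0.70  0.20
productivity_T         0.44  0.37  0.51  0.26
local demography: 7%  immigration: 93%
```

Reading this: Old breeders on Short sites succeed in 80% of attempts
[95% CI 0.77–0.82] and successful sites fledge 2.9 young; 13% of
Short-born fledglings recruit locally.  Apparent immigrants make up 45% of
the population each year, the population is roughly stationary (geometric
mean growth 1.01), and Short sites return 0.64 breeders per breeder per
year against 0.44 on Tall sites — Short outproduces Tall.  The transient
LTRE attributes most of the variance in annual growth to apparent
immigration (the unconstrained residual), with the local-demography part
dominated by Short-habitat rates.

The elasticity and scenario tools answer the prospective question:

```python
from habitatipm.elasticity import elasticity_analysis, scenario_analysis
el = elasticity_analysis(draws)          # yearly +0.001 perturbations
sc = scenario_analysis(draws, [0, 0, 18, 0])   # maintain 18 extra O_S sites
```

## Command line

```
habitatipm simulate --seed 1 --outdir out/
habitatipm fit --indir out/ --chains 3 --iter 3000 --burnin 1000
habitatipm summarize --indir out/
habitatipm ltre --indir out/
habitatipm elasticity --indir out/
habitatipm scenario --indir out/ --added 0,0,18,0
habitatipm run-all --seed 1 --outdir out/
```

Every command writes a JSON run manifest (seed, config, input digests,
convergence flags).  CSV schemas and the event-code dialects are
documented in `habitatipm/io.py`: adult events are 0 = not seen,
1/2/3 = seen in Short (successful/failed/unknown), 4/5/6 = the same in
Tall; juvenile events are 0 = not seen, 1/2 = seen breeding in
Short/Tall.

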