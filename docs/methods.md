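# Methods

## The model

`habitatipm` implements a Bayesian integrated population model (IPM) for a
territorial bird population breeding in two habitat classes — "Short"
(permanently short ground vegetation through the breeding season) and
"Tall" (vegetation growing tall) — with two age classes of breeders
(Young = one year old, Old = older).  The population vector follows the
fixed class order (Y_S, Y_T, O_S, O_T).  The deterministic skeleton is

    NB_{t+1} = A_t NB_t + Im_{t+1},

where `A_t` is the annual 4×4 projection matrix and `Im` the apparent
immigrants — the residual inflow that local survival and recruitment do not
explain.  Breeding success `b` conditions both pathways of the matrix: the
fecundity entries are `b·fled·phi_fl·psi_fl` (success × modeled-sex brood
size × first-year apparent recruitment by natal habitat × natal-to-breeding
settlement) and the adult entries are
`b·phi_succ·psi_succ + (1−b)·phi_fail·psi_fail` (success-conditional
apparent survival, then the success-matched between-year habitat
transition).  `fled` is the per-modeled-sex mean brood size, half of the
total brood under the even-sex-ratio assumption.  Survivors age Y→O after
one season, so only Old breeders appear in the adult rows' destinations.

Four data streams inform the joint posterior:

1. **Breeding success trials**: successes `B` out of monitored sites `R`
   per year/age/habitat, binomial in `b`.
2. **Fledgling counts**: at the successful sites with known brood size,
   `F − S ~ Poisson(S·(2·fled − 1))` — shifted because a successful brood
   holds at least one fledgling.
3. **Adult multi-event mark–resight histories** with state uncertainty:
   hidden states (age, habitat, success) plus dead; events code "not
   seen", "seen with success known" (probability `p·c`) or "seen, success
   unknown" (`p·(1−c)`).  The likelihood marginalizes the hidden states
   exactly with the forward algorithm, conditioning on the known
   first-capture state.
4. **Territory counts** `y ~ Poisson(NB)`, a state-space model whose
   latent process draws recruits as Poisson flows (tracked by natal and
   settlement habitat), survivors as per-source-class multinomials over
   (stay, switch habitat, die), and immigrants as Poisson arrivals per
   class-year with expectation `max(imm_mean, 0)`.

Year-varying rates (`b`, `fled`, `phi_fl`, `phi_succ`, `phi_fail`) get
independent random year effects on the link scale (logit, except log for
`fled`): value = mean + Normal(0, SD).  Habitat transitions, `p` and `c`
are constant through time.  Priors: Normal(0, sd 1/√0.001) on link-scale
means and transition logits, Uniform(0, 10) on the temporal SDs,
Uniform(0, 1) on `p` and `c`, Uniform(−5, 20) on each class-year
immigration mean (the latent Poisson rate is `max(mean, 0)`, so the
negative range is effective prior mass on "no immigration"), and
Normal(first-year count, sd 1/√0.01) truncated at zero for the initial
latent class sizes.

## Sampler

No probabilistic-programming backend is used; the package ships its own
adaptive Metropolis-within-Gibbs engine (numba-compiled).  Design points:

- **Non-centered year effects** (mean, SD, standard-normal deviates) with
  two interweaving moves per family and sweep — a translation move
  (mu ↦ mu+δ, z ↦ z−δ/σ) and a rescale move (σ ↦ σe^δ, z ↦ ze^{−δ}) that
  hold the realized annual rates fixed and therefore only touch the
  prior.  These break the mean–deviate and SD–deviate posterior ridges
  that otherwise stall mixing.
- **Blocked random-walk proposals** (grouped means, grouped SDs, one
  z-vector per family, transition logits, (p, c)) with Robbins–Monro
  scale adaptation toward 30% acceptance during burn-in only.
- **Exact marginalization of the CMR hidden states** via the forward
  algorithm; identical capture patterns are aggregated with weights and
  each history's forward pass stops at its last sighting, with the
  probability of never being seen afterwards supplied by a shared
  backward ("chi") recursion.
- **Single-site integer moves** (±1, ±2) for the count-process latents
  (initial sizes, recruit flows, survivor flows, immigrants).  A latent at
  period t only affects the process terms at t and t+1 and the year-t+1
  count, so acceptance ratios use those local terms only.
- Immigration means are updated single-site against their one Poisson
  term.

Defaults are test-scale — 3 chains, 3,000 iterations after a 1,000
burn-in, no thinning (roughly half a minute on the default study) —
chosen so the reported annual rates and their across-year means converge
(split-R̂ < 1.1); `scale="reporting"` switches to 30,000 kept iterations
after a 10,000 burn-in with thinning 3.  At test scale a few weakly informed
temporal-SD hyperparameters (notably for failed-breeder survival) can
retain R̂ up to ≈1.3–1.4; the diagnostic reports them and the run manifest
flags them rather than hiding them.  Initialization is moment-based
(empirical success fractions, brood means, resighting returns; latent
flows walked forward through the counts with the residual absorbed into
the immigrants), with up to six jittered retries if the joint density is
not finite at the start.

## Synthetic data generator

The generator is an individual-based simulator that reproduces the
statistical structure the IPM assumes: every breeder succeeds, fledges,
survives and moves individually (demographic stochasticity); broods fledge
`1 + Poisson(2·fled − 1)` young in total, each of the modeled sex with
probability 1/2; immigrants arrive as Poisson counts per class.  The
observation layer thins and distorts the truth exactly as the model
expects: binomial monitoring of breeding success, a known-brood subsample,
detection `p` and state certainty `c` for the event histories, Poisson
count error.

Defaults are the study conditions: 24 years; initial counts
(18, 14, 36, 20); the long-term study population's point-estimate vital
rates as generating means; link-scale temporal SDs back-transformed from
its temporal CVs (logit-scale SD ≈ CV/(1−mean), log-scale SD ≈ CV);
immigration means sized so the apparent-immigration rate is ≈0.44 of the
population, with lognormal year variation (SD 0.6) matching the reported
immigration CVs.  No estimates are available for the habitat
transitions, `p` or `c`; the defaults (strong breeding-site fidelity for
successful breeders, weaker and Short-biased movement after failure, a
Short natal preference, `p` = 0.90, `c` = 0.91 — the fraction of monitored
sites with known success) were fixed once as field-realistic values.  The
master seed default is 20190205.

What the generator does *not* emulate: spatial territory structure,
density dependence, within-season renesting, sex-linked dispersal, or
overdispersed vital-rate variation beyond the modeled year effects.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to real-data
misspecification.  Two deliberate simplifications: how unringed immigrants
enter the marked sample is unknown in the field protocol, so the simulator
marks a configurable fraction of new breeders at their first certain
detection (default 0.5, giving study-like history counts); and fledglings
ringed in the nest never re-enter the adult first-capture pool when all of
them are ringed.

## Retrospective and prospective analyses

**Transient LTRE.**  Realized growth is written as
λ_t = Σ_j colsum_j(A(θ_t))·n_{j,t} + Σ_k ω_{k,t}, with `n` the class
proportions and ω the class-wise immigrants at t+1 per individual at t.
Sensitivities are central finite differences (step 1e−6) at the
across-year means of one posterior draw's realized values; the
contribution of θ_i is Σ_j cov(θ_i, θ_j)·s_i·s_j, so contributions sum to
the first-order variance of the reconstructed λ series and covariation is
kept.  A parameter with zero temporal variance contributes exactly zero
(constant series are excluded from the covariance by construction to
avoid round-off).  Note the decomposition targets the reconstructed λ
(the demographic-noise part of the latent process is absorbed by the
immigration and structure arguments), which is what the completeness
check compares against.  Year-specific contributions are
(θ_{i,t+1} − θ_{i,t})·s_{i,t} with the sensitivity at the earlier year;
they are first-order and ignore covariation by construction.  Shares are
normalized by the summed contribution (all parameters) and, within local
demography, by the local sum.

**Real-time transient elasticities.**  Each parameter is increased by
δ = 0.001 in every year; the deterministic trajectory is re-propagated
from the realized year-1 state with the realized immigrant numbers held
fixed (unless immigration is the perturbed quantity), and the response of
the log geometric mean growth is scaled by θ̄/δ.  The raw additive
response is stored alongside.  Perturbed probabilities are clipped to
[0, 1] and flagged.  Structure and immigration perturbations are per
capita (δ·N_t added sites or immigrants per year).  Occupancy
manipulations — both the `n` perturbations and the scenario tool — are
treated as maintained management: the addition applies at every census
and therefore appears in both the numerator and denominator of the annual
growth rates, so the reported change reflects the subsidized population's
trend, not a one-off transfer.  An alternative reading (accumulate the
perturbation multiplicatively without re-propagation) was considered and
rejected because it cannot express the structure and immigration
perturbations.

## Numerical choices and edge cases

- Boundary likelihoods: `b ∈ {0, 1}` is accepted only when the data are
  consistent with it; a Poisson rate of zero contributes 0 to the
  log-likelihood iff the count is zero, −∞ otherwise.
- `fled` has support (0.5, ∞) through the shifted-Poisson rate; the
  simulator clamps `2·fled − 1` at zero.
- Extinction in the simulator is flagged, not an error; the fit refuses
  to start only if no finite initialization is found.
- The LTRE/elasticity matrix fast path (`matrix_from_theta`) is verified
  against the reference `build_projection_matrix` in the tests, as are
  the numba likelihood kernels against the plain NumPy implementations
  and against exhaustive hidden-path enumeration.
- Geometric means of productivity guard zero years with a 1e−9 floor.

## Problem sizes used by the test suite

Tests run the full 24-year default study.  Parameter-recovery checks use
20 replicate studies fitted with 2 chains × (800 burn-in + 1,600 kept)
iterations; the LTRE/elasticity posterior summaries subsample 150–400
draws.  These sizes were chosen as the smallest that leave the checked
summaries' Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- Apparent immigration is a residual; with unconstrained class-year
  means it absorbs every unmodeled source of count variation, and its
  Uniform(−5, 20) prior truncates the largest arrival years under
  study-scale immigration, biasing yearly immigrant totals slightly
  downward (the rate ω is much less affected).
- Temporal-SD hyperparameters of weakly informed survival families mix
  slowly at test-scale chain lengths.
- The LTRE is first-order; with large year effects the completeness
  ratio degrades quadratically in the CVs.
- The female-based two-class model variant is out of scope.
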