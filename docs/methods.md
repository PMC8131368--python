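# Methods

## The model

`ewalearn` implements a dynamic, individual-level learning model for
open-diffusion experiments: a group is given a novel task with several
candidate techniques (here labelled CMS, CMT, CH), every manipulation bout is
recorded with its actor, technique, binary outcome and the set of attending
conspecifics, and the question is which mixture of individual learning and
social-learning strategies best predicts each individual's behavioural
sequence.

Experience-weighted attraction (EWA) dynamics track, per individual `j` and
technique `i`, an attraction score updated after each of `j`'s own bouts:

    A_ij,t+1 = (1 - phi_j) A_ij,t + phi_j pi_ij,t

with `pi` the realised payoff (1 success, 0 failure) and `phi in [0,1]` the
weight of recent over accumulated experience.  Only the chosen technique's
attraction is updated; all attractions start at 0, so the first choice is
uniform regardless of the sensitivity parameter.  Individual choice is
softmax in the attractions with sensitivity `lambda >= 0`:

    I_ij = exp(lambda_j A_ij) / sum_k exp(lambda_j A_kj)

Social information enters through the demonstrations the individual attended
in a sliding window (default 20 min; 5/10/30 supported) before its bout.
With `N_i` the windowed count of attended demonstrations of technique `i` and
`kappa_k,i` the windowed mean of cue `k` (observed payoff, demonstrator rank,
relatedness to the demonstrator, adult-female demonstrator indicator,
same-sex demonstrator indicator), social choice is

    S_ij  propto  N_i^(f_c) exp( sum_k beta_k kappa_k,i )

and realised choice probability is the convex combination

    Pr(i) = (1 - gamma_j) I_ij + gamma_j S_ij,      gamma in [0,1].

`f_c` is the frequency-dependence exponent (1 = proportional imitation,
\>1 conformity, <1 anti-conformity).  Techniques unobserved in the window get
zero social support (`0^f_c = 0`); when nothing was observed at all, `S` is
undefined and the bout is modelled as pure individual choice rather than
dropped, which keeps pointwise likelihoods comparable across model variants.

Eight variants are fitted: individual learning only; frequency dependence
(free `f_c`, no cue coefficients); five single-cue models (payoff, rank, kin,
adult-female, same-sex bias; `f_c` fixed at 1); and a global model with all
cues and free `f_c`.

## Hierarchical structure and priors

Each free learning parameter has a link-scale linear predictor per
individual: population mean + adult offset + male offset + correlated
individual varying effect + correlated group varying effect.  Links are log
for `lambda` and `f_c`, logit for `phi` and `gamma`, identity for the betas;
they enforce the parameter bounds while sampling unconstrained.  Varying
effects are non-centred: `u_j = diag(sigma) L z_j` with `z_j ~ N(0, I)`,
`sigma` the per-parameter scales and `L` the Cholesky factor of a correlation
matrix; all free parameters of a variant co-vary within a block (the exact
correlation structure was an open design choice; one full block per level is
the least arbitrary option and is what we document and test).  With a single
group in the design, group effects are dropped — two additive intercepts for
one group are unidentifiable.

Priors are regularising: normal(0, 1.5) on population means (on the log
scale this spans sensitivities from roughly 0.05 to 20 and, on the logit
scale, rates from 0.01 to 0.99 at 95% prior mass — wide enough to cover the
parameter magnitudes typical of field diffusion experiments, while still
shrinking extremes), normal(0, 1) on age/sex offsets, exponential(1) on
scales, LKJ(4) on correlations.  A tighter normal(0, 1) mean prior was
rejected on prior-predictive grounds: it places attraction sensitivities
above ~7 and recency weights below ~0.06 — values squarely in the plausible
range for this kind of experiment — in its extreme tail, and in recovery
simulations it visibly dragged `lambda` down and `phi` up along their shared
likelihood ridge.

Class-level reports (female/male/juvenile/adult) apply the inverse link to
the class predictor and average over the empirical distribution of the other
factor; the `population` selector reports the baseline cell (juvenile
female).  Four fully free age-sex cells per parameter would not be
identifiable alongside individual and group effects at these sample sizes,
hence additive offsets.

## Sampler

No external probabilistic-programming backend is used: the posterior is
explored with an in-package Hamiltonian Monte Carlo sampler (leapfrog
integration, diagonal mass matrix adapted over expanding warmup windows,
dual-averaging step size, jittered path lengths up to `max_leapfrog`,
energy-error divergence check at |dH| > 1000).  The likelihood gradient is
analytic: the attraction recursion contributes through a companion recursion
for dA/dphi, the softmax/social terms are differentiated in closed form
inside a numba kernel, and the chain rules through links, varying effects
and the correlation-factor transform are applied in numpy.  Gradients are
verified against finite differences in the test suite, and the kernel's
pointwise log-likelihood against an independently coded pure-python
recursion.

Defaults: 2 chains, 500 warmup + 500 kept draws, target acceptance 0.85,
`max_leapfrog` 48.  Convergence is reported as split R-hat and ESS (via
arviz) over all population-level scalars, plus the divergence count.  If
split R-hat exceeds 1.1 (a stuck or maladapted chain), the fit is retried
deterministically with longer warmup and a higher acceptance target (the
`adapt_delta` idiom), up to twice, and the best attempt is kept.  With
only two groups the population-mean and group-effect directions for `lambda`
and `phi` are weakly identified (only their sums are well constrained), and
those directions mix slowly; the two-group analysis scripts therefore default
to a 0.95 target acceptance, longer trajectories and longer chains, and the
identified class contrasts should be read in preference to raw population
means there.

## Model comparison and prediction

WAIC is computed on the deviance scale from the pointwise log-likelihood
matrix: `lppd_e = log mean_draws exp(ll)`, `p_e = var_draws(ll)` (sample
variance, ddof = 1), `WAIC = sum_e -2(lppd_e - p_e)`, with the standard
error from the pointwise deviance terms and Akaike-style weights
`exp(-dWAIC/2)` renormalised.  HPDI is the narrowest contiguous interval of
sorted draws containing `ceil(mass * n)` draws (default mass 0.89), ties
broken toward the lowest lower bound.

Posterior predictions are one-step-ahead: for each draw the forward model is
run along the observed sequence (attractions updated with realised outcomes,
cues as observed) and per-bout technique probabilities are aggregated to
population-daily, individual-daily or per-bout resolution with raw daily
frequencies overlaid.  Free-running prediction (simulating choices forward)
is deliberately not offered: it would require a payoff model at prediction
time and conflates measurement with simulation; the generator covers that
use case.

## The synthetic-data generator

`ewalearn.simulate` is the forward twin of the likelihood plus an
observation-process model for everything the likelihood conditions on:

* two groups of 34 and 19 (infants counted as juveniles) on 11- and
  10-session schedules of ~46 min, ~300 and ~15 bouts per session
  respectively (matching the order-of-magnitude participation asymmetry of
  the motivating experiment);
* technique success probabilities 0.47 / 0.08 / 0.05 (the observed success
  shares of the three techniques in the larger group);
* actor sampling proportional to `rank^skew` (default skew 1), so low
  rankers may never participate; ranks are distinct values spanning [0, 1],
  assigned independently of age and sex;
* attendance: each groupmate watches a bout with probability
  `base * actor_rank^attention` (defaults 0.4 and 1) — the field attendance
  process is unobserved, so this rank-scaled Bernoulli model is an explicit
  assumption surfaced in the config;
* kinship by pedigree rule: juveniles attach to a random adult female
  (r = 0.5), same-matriline otherwise r = 0.25, across matrilines (and for
  immigrant adult males) r = 0;
* true parameters: population values with optional link-scale age/sex
  offsets and individual heterogeneity; defaults lambda = 8, phi = 0.06,
  gamma = 0.3, beta_pay = 1 under the payoff-bias variant.

Innovation is emergent (the first lucky success), not scripted.  Every
event's full choice-probability vector is recorded in a ledger; the test
suite requires the likelihood to reproduce it exactly, so generator and
estimator provably share one forward model.  All randomness derives from a
single seed through fixed substreams (population, parameters, schedule,
choices), making runs byte-reproducible.

What the generator does not emulate: spatial structure and monopolisation of
the food source, demographic turnover, observation/coding error, per-
individual skill differences in success probability, and any attendance
dynamics beyond rank.  Passing recovery tests therefore shows the estimator
is correct and informative *under the assumed observation process*, not that
the assumptions hold in any particular field data set.

## Test and verification sizes

The heavy checks run at a deliberately chosen scale: parameter-recovery and
model-selection tests use five 30-agent worlds of ~2000 bouts (population
truth lambda = 8, phi = 0.06, gamma = 0.3, beta_pay = 1) fitted with
2 chains x 500 draws, plus three gamma = 0 worlds fitted with the global
variant; the likelihood oracle uses 100 random logs of up to 10 events at
1e-10 tolerance.  Coverage is asserted at the 89% HPDI level in at least 4
of 5 replicates per population parameter.

## Known limitations

* Payoffs are binary; graded payoffs (e.g. handling time) would need a
  different attraction update and cue definition.
* `lambda` and `phi` share a likelihood ridge (faster forgetting can mimic
  higher sensitivity); with few bouts per individual their class-level
  posteriors leans on the priors.
* With two groups, group-level scales are informed by two observations per
  parameter and are mostly prior; the same caution applies to any real
  two-group design.
* WAIC standard errors use the independent-pointwise approximation; paired
  dWAIC errors are not reported.
* The sampler is static-trajectory HMC, not NUTS; strongly funnel-shaped
  posteriors need the higher target-acceptance settings exposed in the API.
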