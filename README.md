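# ewalearn

Hierarchical experience-weighted attraction (EWA) models for open-diffusion
experiments: which social-learning strategies spread a novel technique
through an animal group?

## The problem

In an open-diffusion experiment a group is offered a novel resource (e.g. a
food that needs extracting) with no trained demonstrator.  Every
manipulation bout is logged with its time, actor, technique, success or
failure, and the set of conspecifics attending.  The analytical question is
not just *whether* social learning occurred, but *which strategies* —
payoff-biased, rank-biased, kin-, sex- or female-biased, frequency-dependent
— individuals combine with their own trial-and-error experience, bout by
bout.

`ewalearn` is for behavioural ecologists and cultural-evolution researchers
with such event logs (or who want to simulate them).  It provides the data
model, dynamic social-cue construction, the forward learning model, fully
Bayesian hierarchical estimation and WAIC model comparison, plus an
agent-based generator so the entire pipeline is testable with known ground
truth.

## The model

Per individual `j` and technique `i`, attraction scores accumulate personal
payoffs `pi` (1 = success, 0 = failure):

    A_ij,t+1 = (1 - phi_j) A_ij,t + phi_j pi_ij,t

Individual choice is softmax with sensitivity `lambda_j`; social choice
weighs the demonstrations attended in the preceding time window (default
20 min) through observation counts `N_i` and cue means `kappa_k,i`:

    I_ij  = exp(lambda_j A_ij) / sum_k exp(lambda_j A_kj)
    S_ij  propto  N_i^(f_c) exp( sum_k beta_k kappa_k,i )
    Pr(i) = (1 - gamma_j) I_ij + gamma_j S_ij

Cues: mean observed payoff, demonstrator rank, relatedness, adult-female
and same-sex indicators.  Eight model variants (individual-only, frequency
dependence, five single-bias models, global) are fitted hierarchically —
log/logit links, age and sex offsets, correlated individual- and group-level
varying effects — with an in-package Hamiltonian Monte Carlo sampler using
analytic gradients, and compared by deviance-scale WAIC.  See
`docs/methods.md` for the full specification.

## Worked example

The `analysis/` scripts run the whole pipeline on a synthetic two-group
experiment (34 + 19 individuals, payoff-biased truth with gamma = 0.3,
beta_pay = 1):

```bash
python analysis/01_simulate_diffusion.py     # -> results/synthetic/
python analysis/02_fit_models.py             # -> results/fits/<spec>/
python analysis/03_compare_models.py         # -> results/waic_comparison.csv
python analysis/04_report_parameters.py      # -> results/parameter_summary.csv + figure
```

Step 1 prints the generated data's shape — note the realistic group
asymmetry and that the high-payoff technique (CMS) dominates:

```
simulated 3423 manipulation events, 53 individuals
  KB: 147 manipulations; success shares CMS 18.4%, CMT 4.8%, CH 1.4%
  NH: 3276 manipulations; success shares CMS 39.3%, CMT 0.5%, CH 0.2%
participants per group: {'KB': 18, 'NH': 33}
```

Step 3 ranks the fitted variants; the generating strategy wins and
individual learning alone is decisively rejected:

```
                waic     se  dwaic  weight
model
payoff_bias  3186.65  94.22   0.00    0.63
global       3188.07  94.74   1.42    0.31
freq_dep     3191.36  94.46   4.71    0.06
rank_bias    3197.24  93.80  10.59    0.00
individual   3249.09  95.11  62.43    0.00
```

A lower WAIC means better out-of-sample prediction of the bout-by-bout
choices; the weight is the relative support of each variant.  Step 4 writes
posterior means and 89% HPDIs per age class and sex for every parameter
(the social-weight estimates bracket the generating gamma = 0.3, e.g.
0.25–0.34 across classes in the payoff-bias fit) and plots daily predicted
technique probabilities against the raw frequencies.

With only two groups, the split between population means and group effects
is weakly identified for `lambda` and `phi` (only their sums are well
constrained); those directions mix slowly and the class-level contrasts are
the quantities to interpret.  Diagnostics (split R-hat, ESS, divergences)
are printed with every fit and stored in each fit's `fit.json`.

The same pipeline is scriptable from a config file via the CLI:

```bash
ewalearn simulate --config config.yaml --seed 5 --out data/
ewalearn fit      --config config.yaml --data-dir data/ --specs individual,payoff_bias --out fits/
ewalearn compare  --fits fits/
ewalearn report   --config config.yaml --data-dir data/ --fits fits/ --out report/
```

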