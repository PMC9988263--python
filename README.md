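# rlddm — hierarchical RL-DDM analysis of pain-relief gambling

`rlddm` models behaviour in a probabilistic pain-relief gambling task
("wheel of fortune"): on each trial a subject bets on one of two colours,
one of which wins pain relief (−3 °C off a tonic painful heat stimulus)
with 75% probability and the other with 25%; losing raises the temperature
by +1 °C. The package is written for computational-psychiatry /
behavioural-neuroscience researchers who want to (a) fit hybrid
reinforcement-learning drift-diffusion models to such choice + reaction-time
data, (b) compare model variants by cross-validated predictive accuracy,
and (c) link the resulting trial-wise prediction errors to endogenous pain
modulation under different drug conditions (placebo, levodopa, naltrexone).

## The model

Expected values of the two colours are learned by a prediction-error rule
with dual learning rates and an individual outcome sensitivity,

    δ_t = ρ·R_t − Q_chosen,t ,   Q ← Q + η⁺δ_t (δ_t > 0)  or  Q + η⁻δ_t (δ_t ≤ 0),

and choices/RTs follow a Wiener diffusion whose trial drift is the (linear
or sigmoid-saturated) scaled value difference:

    ν_t = (Q_high − Q_low)·ν      or      ν_t = 2ν_max/(1+e^{−(Q_high−Q_low)·ν}) − ν_max .

The 2 × 2 grid (static ρ=1 / scaled ρ) × (linear / sigmoid) defines model
variants 1–4. All parameters are estimated hierarchically (group intercept +
drug main effects + correlated subject deviates, non-centered) by adaptive
Hamiltonian Monte Carlo over an analytic-gradient Wiener first-passage
likelihood. Variants are compared by K-fold (subject-wise) cross-validated
expected log pointwise predictive density (ELPD), with |ΔELPD| ≥ 2·se as
the decision rule. See `docs/methods.md` for the full specification.

A synthetic-cohort generator reproduces the task structure (28 subjects × 3
drug sessions × 45 trials, 75/25 contingency, outcome-matched passive
controls) and couples simulated pain-modulation readouts to the agent's
prediction errors, so the complete pipeline runs and is tested without any
external data.

## Worked example

```python
from rlddm import RLDDM, GenerativeConfig, TaskConfig, generate_cohort
from rlddm.modulation import choice_preference, compute_modulation, fit_pe_model

# synthetic study-scale cohort: 28 subjects x 3 drugs x 45 trials
trials = generate_cohort(GenerativeConfig(), TaskConfig(), seed=1)

cp = choice_preference(trials, blocks=(4, 5), drug="placebo")
print(f"placebo late-block preference: {100*cp.mean:.1f}% (SD {100*cp.sd:.1f}%), "
      f"above chance: {cp.above_chance}")

res = RLDDM(trials, spec=4).fit(profile="desk", seed=1)
print(res.summary().loc[["mu_eta_pos", "mu_alpha", "mu_nu"]].round(3))

ppc = res.posterior_predict(TaskConfig(), n_rep=200, seed=2, drug="placebo")
print(f"PPC mean high-contingency proportion: {ppc.mean:.3f} "
      f"[{ppc.interval.lower:.3f}, {ppc.interval.upper:.3f}], "
      f"observed {ppc.observed:.3f}")

records = compute_modulation(trials).merge(
    res.extract_pe()[["subject_id", "drug", "trial_index", "pe"]],
    on=["subject_id", "drug", "trial_index"])
fit = fit_pe_model(records, outcome_measure="beh")
print(f"behavioural PE slope: {fit.pe_slope:.3f} "
      f"CI [{fit.pe_ci[0]:.3f}, {fit.pe_ci[1]:.3f}]")
```

prints (about a minute, most of it the hierarchical fit):

```
placebo late-block preference: 66.1% (SD 18.6%), above chance: True
             mean     sd  hdi_2.5%  hdi_97.5%   rhat     ess
parameter
mu_eta_pos -1.564  0.991    -3.364      0.273  1.389   4.576
mu_alpha    0.299  0.025     0.247      0.346  1.063  24.534
mu_nu      -0.048  0.199    -0.450      0.307  1.047  76.470
PPC mean high-contingency proportion: 0.630 [0.567, 0.701], observed 0.661
behavioural PE slope: -0.071 CI [-0.125, -0.017]
```

The preference of ~66% says the cohort learned to favour the
high-contingency colour; the group-level posterior locations (unconstrained
scale) bracket the generating population values (η⁺ location −1.6, α
location 0.3, ν location 0.1) — note the honest R̂ of 1.39 on the weakly
identified learning-rate location at this cheap desk profile (use
`profile="paper"` for inference-grade chains); the posterior predictive
proportion brackets the observed statistic; and the negative PE slope means
that the more unexpected a relief, the stronger the measured pain
inhibition — the behavioural coupling the cohort was generated with
(−0.06 °C per PE unit).

The same stages are available from the shell:

```bash
rlddm simulate --out trials.csv --seed 1
rlddm fit --data trials.csv --out fit.npz
rlddm pe --data trials.csv --fit fit.npz --out pe.csv
rlddm modulation --data trials.csv --pe pe.csv --out mod/
rlddm kfold --data trials.csv --k 4 --out kfold.json
rlddm report --data trials.csv --out report/
```

## Layout

```
src/rlddm/
  tasks.py         synthetic schedules, RL-DDM agent, pain coupling
  rl.py            dual-learning-rate value updates, PE series
  wiener.py        first-passage density (+ gradients), diffusion simulator
  hierarchical.py  priors, transforms, log posterior + analytic gradient
  sampling.py      adaptive HMC
  model.py         RLDDM / RLDDMResults (fit, summary, diagnostics)
  crossval.py      subject-wise K-fold ELPD, comparison rule
  analysis.py      HDI, drug contrasts, PPC, PE extraction
  modulation.py    test-minus-control modulation, mixed models, preference
  io.py            canonical CSV schema, validation, YAML config
  cli.py           command-line pipeline
```
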