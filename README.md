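# cudn

Model-based analysis of choice under uncertainty when wrong choices can draw
social blame.

In many decisions we are unsure which option is better, and uncertainty
injects noise into our choices — *uncertainty-induced decision noise* (UDN),
the driver of random exploration. When a wrong choice is likely to be
punished socially (blamed), people can suppress that noise and choose more
carefully, at a cost to their mood. `cudn` implements the full computational
pipeline for studying this mechanism in a probabilistic reversal-learning
task: task simulation, the CUDN (control of uncertainty-induced decision
noise) model and its 15 competitors, per-subject MAP fitting with Laplace
model evidence, random-effects Bayesian model selection with protected
exceedance probabilities, an ideal Bayesian observer benchmark, and the
behavioural statistics (blame-block contrasts, reversal-locked curves,
parameter–performance correlations, mood analysis).

It is aimed at computational cognitive scientists who want to simulate the
task, run parameter/model-recovery studies, or apply the same models to
their own trial-level session tables.

## The model

Two learners run in parallel. A three-level binary hierarchical Gaussian
filter (HGF) tracks p(correct|cue): level 2 carries the logit-scale tendency
(mean μ₂, variance σ₂) and level 3 its log-volatility, giving trial-wise
predictions μ̂₁ = logistic(μ₂) and an estimation uncertainty. A
Rescorla–Wagner rule tracks the conditional blame probability
p(blame|w) ← p(blame|w) + α·(blame − p(blame|w)), updated only on
wrong-choice trials.

Choices follow a softmax over the cues' predicted correct probabilities with
inverse temperature

    β⁽ᵏ⁾ = exp( β₀ − (ζ − ν·p(blame|w)⁽ᵏ⁾) · u⁽ᵏ⁾ )

where u⁽ᵏ⁾ is the estimation uncertainty of the decision variable (maximal
right after probability reversals), ζ ≥ 0 sets the strength of UDN and ν the
degree to which the blame belief suppresses it, in exact proportion to the
current uncertainty. The 16-model comparison space crosses the blame effect
(none / value / noise-independent / noise-interaction) with HGF depth (2/3)
and blame learning (RW / fixed); the CUDN model is
(noise-interaction, 3-level, RW).

See `docs/methods.md` for the update equations, priors, the RFX-BMS
machinery and all design decisions.

## Worked example

```python
import cudn

# simulate four agents governed by the CUDN generative model
sessions, truths = cudn.simulate_cohort(4, seed=2)

# fit four representative models per subject and compare them
from cudn.response import enumerate_model_space
wanted = {"noise_interaction_hgf3_rw", "noise_independent_hgf3_rw",
          "value_hgf3_rw", "none_hgf3_rw"}
specs = [m for m in enumerate_model_space() if m.name in wanted]
evidence, fits = cudn.fit_cohort(sessions, specs, n_restarts=2, seed=2)
result = cudn.run_bms(evidence, n_samples=100_000, seed=2)
print(result.to_frame().round(3))
print("best:", result.best_model, " BOR:", round(result.bor, 3))
```

Output (from `python examples/fit_and_compare.py`):

```
                           alpha      r     ep    pep
model
none_hgf3_rw               1.388  0.174  0.113  0.213
value_hgf3_rw              1.718  0.215  0.172  0.229
noise_independent_hgf3_rw  2.202  0.275  0.284  0.259
noise_interaction_hgf3_rw  2.692  0.336  0.431  0.298

Bayes omnibus risk: 0.732   best model: noise_interaction_hgf3_rw
```

`r` is each model's posterior expected population frequency, `ep` the
probability that it is the most frequent model, and `pep` the protected
exceedance probability — `ep` shrunk toward uniform by the Bayes omnibus
risk, the posterior probability that all models are equally frequent (high
here, as expected for only four subjects). The generative model comes out on
top even at this tiny scale; the test suite runs the full 30-subject,
16-model recovery.

The other example scripts cover the task generator
(`examples/simulate_task.py`), the ideal-observer benchmark with its hazard
sensitivity sweep (`examples/ideal_benchmark.py`), and the behavioural
statistics pipeline including the mood analysis
(`examples/behaviour_report.py`).

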