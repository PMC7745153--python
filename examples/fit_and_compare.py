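"""Fit candidate models to simulated sessions and compare them with RFX-BMS.

Simulates four CUDN-governed agents, fits four representative models per
subject by MAP with Laplace evidence (the CUDN model, its
uncertainty-independent blame variant, the blame-as-value variant and the
UDN-only baseline), then runs random-effects Bayesian model selection and
prints expected frequencies, exceedance probabilities and protected
exceedance probabilities.
"""

import cudn
from cudn.response import enumerate_model_space

sessions, _ = cudn.simulate_cohort(4, seed=2)

wanted = {"noise_interaction_hgf3_rw", "noise_independent_hgf3_rw",
          "value_hgf3_rw", "none_hgf3_rw"}
specs = [m for m in enumerate_model_space() if m.name in wanted]

evidence, fits = cudn.fit_cohort(sessions, specs, n_restarts=2, seed=2)
print("log model evidence (subjects x models):")
print(evidence.round(1).to_string())

result = cudn.run_bms(evidence, n_samples=100_000, seed=2)
print("\nmodel comparison:")
print(result.to_frame().round(3).to_string())
print(f"\nBayes omnibus risk: {result.bor:.3f}   best model: {result.best_model}")
print("\nr is the posterior expected frequency of each model in the population; "
      "ep the probability it is the most frequent; pep shrinks ep toward "
      "uniform by the omnibus risk that all models are equally frequent.")
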