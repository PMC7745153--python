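# Methods

`cudn` models choice behaviour in a probabilistic reversal-learning task in
which wrong choices are probabilistically punished with social blame. This
note describes the generative task, the learning and response models, the
estimation and model-comparison machinery, the synthetic-data generator and
its calibration, the numerical choices, and the known limitations.

## Task

A session has 240 trials. On every trial the participant chooses one of two
cues; exactly one cue is "correct" each trial. The probability that cue 1 is
the correct one is drawn per block from {0.7, 0.8} when cue 1 is the good cue
and {0.3, 0.2} otherwise (the two cues' correct probabilities always sum to
one — the reciprocal design), and the good cue flips at every block boundary;
block lengths are uniform on 10–50 trials, with the final block truncated at
the session end. Independently of the correct schedule, the conditional
probability of blame feedback after a *wrong* choice alternates between
high-blame blocks (0.8 or 0.9) and low-blame blocks (0.1 or 0.2) of 20–40
trials. Mood is probed every 8th trial on a −3..3 scale, giving 30 probes per
session. Because the reversal/blame structure is only constrained by these
ranges, every generated schedule is a fresh draw; nothing in the package
depends on one particular realized sequence.

Feedback is sampled by drawing the trial's correct cue once (from the cue-1
probability) and comparing it with the choice, so the outcome of the
unchosen cue is implied — the reciprocity that lets every learner observe
"which cue was correct" on every trial regardless of its choice.

## Perceptual model

Two learners run in parallel over a session.

**Correct-probability learning (binary HGF).** A three-level binary
hierarchical Gaussian filter tracks the tendency of cue 1 to be correct.
Level 2 carries the logit-scale tendency with posterior mean μ₂ and variance
σ₂; level 3 carries its log-volatility μ₃. Before each outcome the filter
predicts

    μ̂₁ = logistic(μ₂),   σ̂₂ = σ₂ + exp(κ·μ₃ + ω),

and after observing the outcome it applies the standard variational update
set: the level-2 precision gains the outcome information μ̂₁(1−μ̂₁), and
level 3 is driven by the level-2 volatility prediction error with coupling κ
and step variance ϑ. A two-level variant freezes level 3, leaving a constant
volatility exp(κ·μ₃₀ + ω). For fitting, κ = 1 and the initial states
(μ₂₀ = 0, μ₃₀ = 1, σ₂₀ = σ₃₀ = 1) are fixed; ω and ϑ are free. The level-3
posterior precision can become non-positive in extreme parameter regimes; the
update then raises a `ParameterPathologyError` rather than continuing with a
negative variance (the fitting objective converts this into a large penalty).

**Blame-probability learning (Rescorla–Wagner).** The subjective conditional
probability of blame given a wrong choice, p(blame|w), follows the delta
rule p ← p + α·(blame − p), applied only on wrong-choice trials (blame is
unobservable after a correct choice); the prediction error blame − p is the
blame prediction error (BPE). The initial belief is 0.5. A fixed
(non-learning) blame belief is the special case α = 0 with a free initial
value.

## Response model and decision uncertainty

Choices follow a softmax over the two cues' predicted correct probabilities
with a trial-wise inverse temperature

    β⁽ᵏ⁾ = exp( β₀ − (ζ − ν·p(blame|w)⁽ᵏ⁾) · u⁽ᵏ⁾ ),

the CUDN ("control of uncertainty-induced decision noise") model: estimation
uncertainty u lowers β (uncertainty-induced decision noise, UDN, with
strength ζ ≥ 0), and the blame belief counteracts that effect in proportion
to ν, exactly proportionally to the current uncertainty (∂ log β / ∂ p = ν·u).
ν is sign-free; a negative ν amplifies UDN under blame.

**What u is.** The decision variable of the softmax is the value difference
2μ̂₁ − 1. Its estimation variance, by the delta method, is
4·[μ̂₁(1−μ̂₁)]²·σ̂₂. The covariate used by the response model is this
variance times a unit constant (8):

    u = 32·[μ̂₁(1−μ̂₁)]²·σ̂₂  ∈ (0, ~2.4].

Two deliberate choices are folded in here. First, the uncertainty is
measured on the probability scale of the decision variable rather than as
the raw logit-scale variance σ̂₂: on this task σ̂₂ is nearly constant across
a session (the level-1 precision weight dominates its dynamics and it *dips*
slightly when beliefs pass through 0.5), whereas the probability-scale
uncertainty is maximal immediately after a reversal and decays with
learning — the dynamics the task is designed to create, and the reason an
early-after-reversal analysis window is meaningful. It also makes β₀, ζ and
ν jointly identifiable; with a near-constant covariate they are not. Second,
the unit constant is a scale convention for ζ and ν: it is set so that
suppression strengths ν of order one — the regime the recovery studies
simulate — produce high-vs-low blame performance differences of the size the
behavioural data show. The trajectory object still exposes the raw σ̂₂
alongside u.

**Candidate model space.** Sixteen models arise factorially from
blame effect {none, value, noise-independent, noise-interaction} ×
HGF depth {2, 3} × blame learning {Rescorla–Wagner, fixed}. The
noise-independent family uses log β = β₀ − ζu + ν·p(blame|w) (blame reduces
noise regardless of uncertainty); the value family leaves β unmodulated by
blame and instead gives cue i the utility p(correct|i) + λ·p(wrong|i)·p(blame|w)
with λ expected negative (blame as a prospective negative value); the none
family has no blame influence. For models without a blame effect the
learning factor is inert (both variants are listed; their likelihoods
coincide). CUDN is (noise-interaction, 3-level, RW).

## Estimation and model comparison

**MAP + Laplace.** Each model's free parameters are estimated per subject by
maximizing log-likelihood plus Gaussian log-prior in a transformed space
(log for ζ and ϑ, logit for α and the fixed blame belief, identity
otherwise). Default priors (transformed space): β₀ ~ N(0,2), log ζ ~ N(0,2),
ν ~ N(0,2), λ ~ N(0,2), logit α ~ N(0,1), ω ~ N(−3,4), log ϑ ~ N(−6,4).
Optimization is L-BFGS-B with numerical gradients, multi-start (first start
at the prior mean, the rest prior draws; 8 restarts by default, fewer where
runtime matters — convergence was verified to be start-insensitive on this
problem). The log model evidence is the Laplace approximation at the MAP,
with the Hessian by central finite differences (step 1e−4). When the
Hessian is not positive-definite — which happens when the MAP sits next to a
non-smooth boundary of the objective, e.g. the pathology penalty — its
eigenvalues are clipped into [1e−2, 1e4] before applying the Laplace
formula; a BIC-style evidence is the last resort. The regularization is
applied identically to every model so approximation artifacts do not
masquerade as evidence differences.

**RFX-BMS.** Model identity is treated as a random effect with Dirichlet
prior Dir(1,…,1) over population frequencies. A variational fixed point
yields the posterior concentrations α; exceedance probabilities come from
Monte-Carlo Dirichlet sampling (10⁶ draws by default; the two-model case is
cross-checked against the Beta closed form); the Bayes omnibus risk (BOR)
compares the variational free energy of this model against the null in which
all frequencies are equal; the protected exceedance probability is
PEP = EP·(1−BOR) + BOR/K. Likelihood-ratio invariance (adding a constant to
a subject's row) and column-permutation equivariance are tested properties.

**Prior susceptibility.** Because ν's prior can sway the comparison, the
models containing ν can be refit under a list of (mean, variance) settings
and the BMS rerun per setting, reproducing the robustness analysis design.

## Ideal observer

The benchmark agent knows the generative structure: an HMM filter over the
four latent levels {0.2, 0.3, 0.7, 0.8} of the cue-1 correct probability,
with a constant per-trial hazard h of jumping to one of the two levels on
the opposite side of 0.5 (the Markov approximation of uniform 10–50-trial
blocks; default h = 1/30, the reciprocal mean block length). Each trial it
propagates its belief, chooses, observes the realized correct cue and
performs an exact Bayes update (verified against brute-force path
enumeration on short instances).

Two response policies are provided. The greedy policy (choose the cue with
predictive correct probability above 0.5) is the reward-maximizing upper
bound; it scores ~82% good choices and is nearly flat in the hazard. The
**posterior-matching** policy (choose cue 1 with probability equal to the
posterior probability that cue 1 is the better cue; equivalently, sample a
latent level and act on it — Thompson sampling) is the package's benchmark
default: it is the canonical parameter-free stochastic benchmark, scores
~74% on this task, and sits just above human-level performance as an
"ideal learner" reference should. The hazard and policy are arguments, and
`examples/ideal_benchmark.py` prints the sensitivity sweep.

## Behavioural statistics

A *good* choice is the cue designed to be better in the current block; an
*accurate* choice is one that drew correct feedback. Per subject, good
choice, accuracy and mean RT are computed per blame condition, plus
early-window (first 10 trials after each reversal) variants of good choice
and accuracy. High-vs-low contrasts use two-tailed paired t-tests (Cohen's d,
95% CI of the mean difference) or the Wilcoxon signed-rank test
(matched-pairs rank-biserial effect size) for RT. No multiple-testing
correction is applied across the headline contrasts; they are reported
individually. Reversal-locked good-choice curves (horizon 20, subject-level
bootstrap bands) and the Spearman correlation between fitted ν and the
high-minus-low enhancement of early-window good choice and of accuracy
(full sample and after trimming observations beyond 2 s.d.) complete the
performance analyses. The accuracy contrast is computed on all trials (the
early-window restriction is stated only for good choice); the early-window
accuracy is also reported.

**Mood.** Mood ratings at probe trials are regressed per subject on the
concurrent p(blame|w) with the recent correct rate (last 8 trials) as a
covariate, and the p(blame|w) coefficients are tested against zero at the
group level (one-sample t-test). Subjects with constant mood are excluded
with a logged warning.

## Synthetic cohorts: what the generator emulates and how it was calibrated

`simulate_cohort` draws per-subject parameters from `CohortPriors`
(independent Gaussians in each parameter's fitting space, truncated at 2 s.d.
to stay inside the filter's well-behaved regime), generates an independent
schedule per subject, and simulates choices from the generative CUDN model.
Per-subject RNG streams are spawned from `numpy.random.SeedSequence(seed)`.

Defaults: β₀ ~ N(1.5, 0.4²), log ζ ~ N(log 0.75, 0.5²), ν ~ N(1, 0.5²),
logit α ~ N(−0.4, 0.35²), ω ~ N(−2.6, 0.25²), log ϑ ~ N(log 0.2, 0.3²),
λ ~ N(−1, 0.5²). These were chosen once, by forward simulation, so that the
cohort reproduces the qualitative group behaviour of human participants on
this task: overall good-choice proportion ≈ 0.68–0.70 (humans: 68.2%),
accuracy ≈ 0.59–0.60, a positive early-window good-choice enhancement and a
positive accuracy enhancement in high-blame blocks, and slower responses
under high blame. ν centred at 1 with s.d. 0.5 encodes a population in which
blame expectation suppresses most of the UDN at high blame belief for the
average subject, with meaningful individual variation including a minority
of negative-ν subjects.

**RT and mood generators.** The experiment has no mechanistic RT or mood
model, so the simulator uses simple descriptive ones. RT is log-normal with
location increasing in the deliberation index p(blame|w)·u
(`log rt = log 0.58 + 0.06·D + ε`, ε ~ N(0, 0.25²)) — slower responding when
blame is expected and the decision is uncertain. Mood probes are
`round(clip(m₀ − 2·p(blame|w) + 2·recent-correct-rate + N(0, 0.8²), −3, 3))`,
building in the negative effect of blame expectation on mood. These
generators exist so the RT contrast and the mood analysis are exercisable
end-to-end; passing those tests shows the analysis recovers what the
generator builds in, not that real RT or mood obey these forms.

What the generator does *not* emulate: response lapses and attention drift,
within-session parameter drift, any coupling between mood and subsequent
choices, cue-position biases, and trial-wise RT–choice dependence beyond the
deliberation index.

## Numerical choices

- Exponents κμ₃ + ω and log β are clipped at ±30; μ̂₁ is clamped to
  [1e−12, 1−1e−12]; choice probabilities are floored at 1e−12 inside the
  log-likelihood.
- VB fixed point iterates to an α-change below 1e−8 (hard cap 2000
  iterations, error with trace on non-convergence).
- Exceedance sampling draws in 200k-row chunks; exact ties in the arg-max
  are broken uniformly at random.
- Ideal-observer ties (predictive probability exactly 0.5) are broken
  uniformly.
- Session/cohort simulation, fitting and every Monte-Carlo routine take
  explicit seeds; identical seeds give bit-identical outputs.

Problem sizes used in the test suite were chosen to make each check
statistically decisive at the scale it runs: recovery studies use 30
subjects × 240 trials with 3 optimizer restarts; benchmark and chance-floor
estimates use 200–300 sessions; null calibrations use 200–500 replicates.

## Known limitations

- **β₀–ζ entanglement.** From 240 trials the likelihood constrains the
  combination β₀ − ζ·ū (ū the session-mean uncertainty) much better than β₀
  and ζ separately; their estimate errors correlate ~0.7–0.8 across
  subjects. Rank-recovery of ζ in a 30-subject cohort therefore fluctuates
  around 0.4–0.65 across cohort draws, and β₀ around 0.5–0.8. ν, whose
  information comes from the within-session covariation of blame belief and
  uncertainty, recovers more reliably (~0.6–0.85).
- **2- vs 3-level depth is weakly identified.** On a constant-hazard
  reversal task with κ = 1, level-3 volatility tracking changes choice
  likelihoods little; the (noise-interaction, 2-level, RW) model is a
  near-behavioural twin of CUDN, and their evidence gap per subject is a
  few tenths of a nat. Model selection separates the blame-effect families
  cleanly but decides the depth factor on small margins.
- **The ideal-learner construction is a reconstruction.** Greedy exact
  Bayes scores ~82% on this task under any plausible hazard, well above the
  published ideal-learner reference of ~70%; the posterior-matching policy
  is the closest canonical parameter-free construction (~74%) and is used as
  the benchmark default, with both policies exposed.
- The mood and RT analyses validate the pipeline against the package's own
  descriptive generators, not against mechanistic models of affect or
  response time.
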