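# Methods

## The model

`mutsampler` implements a rational process model of human causal reasoning
over small causal Bayes nets with binary variables. The normative layer is a
standard causal graphical model: each non-root variable `V` with parents
coded +1 (present) / −1 (absent) has

    p(V = 1 | parents) = 1 / (1 + exp(−(Σ_j w_j c_j + w_exo))),

root variables have a direct prior probability, and the joint distribution
over the `2^n` system states is the product of these local terms, computed by
exact enumeration (the networks of interest have 3–4 variables). Multi-parent
influence is the additive extension of the single-parent logistic — the
natural choice when one shared strength parameter ties all generative links,
as the fitted models assume. Conditional probability queries are answered by
summing states.

The process layer — the mutation sampler — assumes that people approximate
these queries by Metropolis–Hastings sampling on the hypercube of system
states, under two resource constraints:

1. **Short chains.** The chain has length λ (typically 10–40 samples), far
   too short for the walk to mix. Predictions are computed as the exact
   *occupancy distribution* — the average of the state distribution over the
   first L steps, i.e. the expectation of the visited-state frequencies —
   rather than by averaging noisy simulated walks. The start state counts as
   the first sample, so λ = 1 returns the start distribution itself: the
   model's resource-starved limit is a pure prototype response. Non-integer λ
   interpolates linearly between adjacent integer lengths, keeping the
   fitting objective continuous in λ.
2. **Biased starts.** Sampling starts at *prototype states*: full
   assignments that are qualitatively consistent with every causal link —
   equal endpoint values across a generative link, opposite values across an
   inhibitory one — ignoring causal direction and link strength. The start
   distribution is the uniform mixture over the prototype set. When no
   assignment satisfies every link (any structure giving one variable both a
   positive and a negative path from the same ancestor, e.g. the diamond
   X→{YA,YB}→Z with exactly one inhibitory link), the prototype set is empty
   and the start is uniform over all `2^n` states — the "no prototype"
   variant of the model.

The MH proposal is the single-variable flip, uniform over variables (1/n
each); acceptance is min(1, π(s′)/π(s)); rejected mass stays on the current
state. This kernel is in detailed balance with the exact joint, so in the
λ → ∞ limit the occupancy converges to the normative distribution and all
predicted reasoning errors vanish. There is deliberately no burn-in and no
thinning: the bias of the early samples *is* the psychological mechanism.

Short prototype-started chains distort the sampled joint toward the
prototypes, and conditionals computed from the distorted joint violate the
Markov condition: on the all-generative diamond, p(Yi=1|X=x, Yj=1) exceeds
p(Yi=1|X=x, Yj=0) even though X screens Yi off from Yj. With a uniform start
the distortion is toward the uniform distribution, which is symmetric with
respect to the screened-off variable's value, so Markov violations largely
disappear — the model's signature prediction for the one-inhibitory-link
diamonds.

## The Markov-violation score

For the diamond, the 12 Markov queries are p(Yi=1|X=x, Yj∈{0, unknown, 1})
for both orderings of (YA, YB) and both values of X. The summary score is the
mean over the four (Yi, x) cells of value(Yj present) − value(Yj absent), on
the 0–100 rating scale (model probabilities are multiplied by 100 first).
**Sign convention:** present-minus-absent, so the classic positive violation
gives a positive score and the normative model scores exactly 0. The score
ignores the battery's other 20 queries.

The full 32-query battery adds a documented default set of predictive and
diagnostic queries over the same four variables (all p(Z|YA,YB), p(X|Yi),
p(Yi|Z), p(X|Z), p(Z|X), p(Z|Yi) combinations). Only the 12 Markov queries
are pinned by the design; the other 20 are replaceable via
`default_battery_32(..., extra_queries=...)` so a deposited query set can be
mirrored exactly.

## Fitting and model comparison

Each subject's ratings are fit by least squares
(Σ(100·prediction − rating)²) under three variants: normative,
sampler-with-prototypes, sampler-without. One parameter `wgen` is shared by
all generative links, one `wexo` by all non-root variables; networks with an
inhibitory link add `winh`; sampler variants add λ. Parameter counts are
therefore 3/4 (normative) and 4/5 (sampler). Bounds: wX ∈ [0.01, 0.99],
wgen ∈ [0, 5], winh ∈ [−5, 0], wexo ∈ [−5, 5], λ ∈ [1, 100] searched on the
log scale (the bound brackets typical fitted group means of 16–36 with
headroom). The optimizer is bounded Nelder–Mead from 20 seeded start points
(one canonical start plus uniform draws in the box), best run kept; with a
fixed seed refits are bit-identical. Models are compared per subject by the
least-squares AIC, `n·ln(SSE/n) + 2(p+1)` (natural log), and group summaries
report the percentage of subjects each variant fits best, with exact AIC
ties split equally. Chain lengths are averaged geometrically
(exp mean log λ) because their distribution is strongly right-skewed.

On networks with an empty prototype set, the prototype variant is still
comparable by imposing the all-generative prototypes (all-present /
all-absent) as the start set (`ModelSpec(assumed_prototypes=...)`;
`condition_model_specs` does this automatically). That is the theoretically
interesting comparison for the inhibitory conditions: do subjects behave as
if those prototypes applied? Note that on data generated by the *unbiased*
sampler the normative model tends to win a three-way AIC comparison — the
unbiased sampler merely approximates it while paying for λ — so recovery
checks for uniform-start cohorts compare the two sampler variants, which is
also the published model-comparison design.

## Group-level statistics

Per-condition Markov-violation scores are analyzed with a one-way
between-subjects ANOVA, two-sided one-sample t-tests against zero, and the
default JZS Bayes factor (Cauchy prior on standardized effect size, scale
√2/2, configurable), computed by adaptive quadrature of the one-dimensional
integral over the prior's mixing variable after mapping (0, ∞) to the unit
interval. Confidence intervals in summaries are classical per-group 95%
t-intervals.

## The synthetic-data generator

Each synthetic subject is: a condition (Generative / YA-Inhibitory /
YB-Inhibitory, fixing the diamond's polarity pattern), a generating model
variant, true parameters, deterministic model predictions for the 32-query
battery, and truncated-Gaussian response noise clipped to [0, 100] — the
simplest response model consistent with a bounded slider. Defaults define
the emulated study conditions: 56/28/28 subjects per condition (112 total,
giving the design's ANOVA dfs of 2 and 109), domain labels rotated with no
modeled effect, Generative subjects generated by the prototype sampler and
Inhibitory subjects by the uniform-start sampler, parameters drawn per
subject from wX ~ U(0.4, 0.8), wgen ~ U(0.2, 1.0), winh ~ U(−1.0, −0.2),
wexo ~ U(0, 1), λ log-uniform on [8, 40] (ranges bracketing the fitted group
averages for this paradigm), and noise sd 10 rating points. Everything is
deterministic under the master seed, which expands to per-subject seeds.

What the generator does *not* emulate: within-subject trial-to-trial
sampling variability (each rating is the deterministic occupancy prediction
plus noise; the stochastic `simulate_chain` exists for such studies but is
not the default response model), individual differences beyond the parameter
ranges, response anchoring or rounding, and domain effects. Passing tests on
synthetic cohorts therefore demonstrate the pipeline's correctness and the
model's internal logic — e.g. that prototype-generated cohorts show positive
mean Markov violations and uniform-start cohorts much smaller ones — not
facts about human data.

## Numerical choices and degenerate inputs

- Exact joints are strictly positive (logistic CPDs, interior priors), so
  the MH kernel is well defined; a zero-mass conditioning event can arise
  only from degenerate *sampled* distributions and returns a configurable
  fallback of 0.5 (the maximally uninformative judgment).
- State indexing: first declared variable is the most significant bit, so
  the lattice labels 0000/1111/110/001 map unambiguously.
- Occupancy distributions are exact up to floating point; detailed balance
  and stationarity hold to 1e-12 in tests.
- AIC of a perfect fit (SSE = 0) returns −inf with a warning.
- Zero within-group variance (ANOVA) and zero sample variance (t-test) are
  errors, not NaNs.

## Problem sizes

Default analysis sizes are small by construction: 16-state lattices, 32-item
batteries, 20 optimizer starts per subject-model pair (≈1 s per fit). The
reproduction script uses the full 112-subject cohort for the score
statistics (no fitting required) and 20 + 12 subjects for the fitted
recovery studies, which keeps a complete run around a minute on one core.

## Known limitations

- Graded prototypes (start probability decreasing in the number of
  inconsistent links) are a documented extension point, not implemented;
  `SamplerSettings(start_mode="custom")` accepts any start distribution as a
  hook.
- The optimizer is a multi-start local search; with rough likelihood
  surfaces a different start grid can find marginally better optima, so
  fitted parameters are comparable across runs only at a fixed seed.
- Chain length is fixed (with interpolation) rather than drawn from a
  distribution with mean λ; the alternative would smooth occupancy in a
  similar way and is not explored here.
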