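# Methods

## Task and generative model

The ASRT stimulus stream alternates a deterministic 4-element pattern
with i.i.d. uniform random stimuli: blocks of 85 trials, the first 5
random warm-ups, then ten repetitions of the 8-element unit
pattern–random–…, re-entering each block at the same phase. Patterns are
identified up to cyclic rotation (6 distinct designs out of 24
permutations). Random trials may repeat any stimulus, including the
upcoming pattern element; warm-up trials are labelled structurally
(`warmup`) so exclusion rules never re-derive positions.

Two-back statistics: marginalizing over the parity of the current trial,
the stimulus two ahead continues the pattern cycle with probability
`½·1 + ½·¼ = 0.625` and lands on each specific alternative with `0.125`.
The package derives these by enumerating the exact 8-state machine at
stationarity rather than asserting the constants. Note that the fraction
of *high-labelled trials* in a blocked session is slightly lower
(50/83 ≈ 0.602) because trials whose two-back context falls in the
warm-up run are high only with probability ¼; the 0.625 value is the
steady-state continuation probability and the label fraction from
index 8 onward.

## Internal model and response-time model

The participant filters a discrete HMM (transitions `π`, emissions `φ`
over the 4 stimuli) and predicts the next stimulus by propagating the
belief one step. Filtering consumes *all* stimuli (warm-ups and error
trials included) and carries the belief across block boundaries; the
default initial belief is the stationary distribution of `π` (uniform
when it is not unique) — the least informative dynamically consistent
choice, and the phase resolves within one pattern cycle regardless.

Reference models:

- **Ideal observer**: the exact 8-state machine (pattern states one-hot,
  random states uniform, deterministic transitions). Its one-step
  observable conditionals are uniform, so a first-order model can learn
  nothing from it. Because the machine is deterministic it assigns
  probability zero to some warm-up runs (e.g. warm-ups `2,3,4,4,1` are
  inconsistent with both alternation parities), so exact filtering of a
  full block can fail; `regularize_hmm` mixes a uniform component
  (default 1e-3) into every row for any use that must filter arbitrary
  sequences, and fixed-model fits apply it automatically. The exact
  constructor itself is unchanged and raises on impossible observations.
- **Markov**: identity-emission HMM; filtering reduces to a row lookup.
- **Trigram**: the two-back predictor emitting 0.625/0.125 (uniform on
  the first two trials of a block). Only the high/low dichotomy is
  meaningful; the values make rank and ROC analyses well defined.

Response times follow LATER: `RT = θ0 + (−log p)/r` with
`r ~ Normal(μ, σ)` truncated at zero. Truncating the *rate* (rather than
the RT) keeps the density closed-form and guarantees `RT > θ0`. Times are
seconds internally; files carry milliseconds. The density includes the
change-of-variables factor `(−log p)/(rt−θ0)²`; `p = 1` is a point mass
at `θ0` and is rejected by the density (the sampler and the plug-in
prediction handle it as `θ0` exactly). Subjective probabilities are
floored at 1e-6 before logs. The exact mode of the density sits at
`θ0 + 2s/(μ + √(μ² + 8σ²))` (`s` the surprise), about 10% below the
plug-in `θ0 + s/μ` at `σ/μ = 0.25`; the plug-in is the default point
prediction, the exact mode an option. The symbols `θ0` and `τ0` name the
same offset parameter.

## Inference

Priors (time in seconds; Gamma as shape–rate, the only reading placing
mass on human RT scales): `τ0 ~ Γ(1, 10)` (mean 0.1 s),
`μ ~ Γ(1, 0.1)` (mean 10 s⁻¹), `σ ~ Γ(1, 0.01)`; emissions
`Dirichlet(0.8, 0.8, 0.8, 0.8)`; transition rows
`Dirichlet(α0/K, …, α0/K, α0/K·ε)` under a truncation at `k_max`
(default 12, comfortably above the 8-state ideal observer), with
`α = 1.3`, `γ = 3.8`, and `α0 = α` (the hierarchy gives `α0` no separate
value). The `ε` in the row prior is the same slicing variable drawn
`ε ~ Uniform(0.02, 0.2)` in the outer Gibbs step; while it is in force,
filtering is restricted to the belief's `1−ε` support (renormalized over
the retained states). `ε = 0` retains everything; prediction always
filters untruncated.

The likelihood is the LATER log-density of each valid-trial RT at the
filtered subjective probability of the realized stimulus. Valid trials
exclude warm-ups, incorrect responses, and RTs below 180 ms; masked
trials still feed the filter. Within a fit, `π` and `φ` are constant;
only the belief evolves trial by trial. Fits are per participant and per
session; the full preset trains on blocks 11–20 and tests on blocks 1–10.

**Sampler.** Between slice steps, the continuous parameters are updated
by an adaptive Metropolis-within-Gibbs sweep: each transition and
emission row receives a Dirichlet proposal centred on its current value
(concentration adapted toward ~25% acceptance during burn-in), with an
occasional independence draw from the prior to allow jumps to
near-one-hot rows, and the RT parameters receive log-space Gaussian
steps. The forward-filter likelihood is compiled (numba) and costs tens
of microseconds, which makes the blocked sweep a practical substitute
for gradient-based inner steps at these model sizes: a desk-scale fit
evaluates the likelihood ~30k times in seconds. LATER parameters are
initialised by moment-matching the training RTs; one chain starts from a
template with near-identity emissions (an informed, overdispersed start
akin to data-driven initialisation in mixture models), the others from
the prior. Chains with a non-finite starting density are re-initialised
and the restart logged. Samples from the second half of each chain are
retained; the last 60 unique samples per chain (consecutive duplicates
collapsed) drive prediction — held-out R² at 60 retained samples is
within 0.01 of its value at 120 on a well-mixed fit.

Presets: **full** = 4 chains × 1600 outer × 30 inner (the reference
protocol); **desk** = 2 × 200 × 5, the configuration used throughout the
test suite and examples, typically with `k_max = 8` and 10-block
sessions (train 6–10, test 1–5). All seeds derive from the fit seed plus
the chain index.

Fixed-model fits (e.g. calibrating the ideal observer's RT parameters)
freeze `(π, φ)`, precompute the per-trial predictions once, and sample
only the three LATER parameters — their 90% intervals cover known ground
truth in ≈90% of replicate fits at desk scale. The Markov fit uses the
same machinery at `K = 4` with identity emissions and rows
`Dirichlet(α0/4)`.

## Synthetic participants

Three ground-truth internal models emulate increasing exposure:
**early** — a 4-state near-Markov model (sharpened random transitions,
near-identity emissions): immediate dependencies only; **middle** — a
6-state hybrid (four softened pattern states, two shared random states)
that knows pattern and random elements alternate but tracks the phase
poorly; **late** — the ideal observer with softened emissions (8%
uniform mixture) and transitions (4%). "Increasing experience" is
operationalized as decreasing mean KL from the ideal observer's
predictions (≈0.79 / 0.66 / 0.06 on a seeded session). An optional
constructor fits an HMM to stimulus streams of chosen length (via EM) to
derive exposure-graded models instead.

RTs are drawn from LATER at the subjective probability of the realized
stimulus. All simulated trials are correct; the error-prediction
analyses are exercised through an explicit semi-synthetic extension that
flips trials to errors where the generating model's subjective
probability is low. The default RT-parameter grid —
`θ0 ∈ {0.12, 0.18, 0.24}` s, `μ ∈ {6, 8, 10}` s⁻¹, `σ ∈ {1, 2, 3}` s⁻¹ —
crosses with the three models into 81 datasets and yields simulated RT
standard deviations from ~30 to well over 100 ms, bracketing practiced
human performance. No RT floor is applied at generation; the standard
mask applies at fit time.

What the simulator does *not* emulate: error commission and
post-error slowing, within-session drift of the internal model or of the
RT parameters, fast guesses below the 180 ms floor, and any explicit
knowledge. Passing recovery tests therefore demonstrates that the
inference machinery works under the stated generative assumptions, not
that those assumptions exhaust real behaviour.

## Evaluation conventions

- **R²**: squared Pearson correlation by default (free slope and
  intercept, required for reference models whose predictions are only
  monotone in RT); the `1 − SSE/SST` variant is also always computable
  and can be negative. Batch outputs report both.
- **KL**: per-trial `Σ_i p_i(log p_i − log p̂_i)` against the task's
  ground truth (1 on the pattern element for pattern trials, ¼
  otherwise), averaged over trials; model probabilities floored at 1e-6
  and renormalized.
- **Error analyses**: ranked-first fractions with fractional tie
  splitting (chance exactly 0.25) and an ROC over the subjective
  probability of the realized stimulus (trapezoid AUC; equals the
  Mann–Whitney statistic with ties at ½). The trigram model's ROC has
  exactly two interior points.
- **Higher-order score**: among trials whose observed triplet is high,
  mean RT difference (random-third minus pattern-third) across matched
  full triplet identities; positive = pattern advantage. Triplets
  straddling block boundaries are excluded; matching is on the full
  observed triplet. The trigram model scores exactly 0 by construction.
- **Decomposition**: OLS of per-trial CT predictions on Markov and
  ideal-observer predictions plus an offset; collinear designs are
  rejected with the condition number reported.

Cohort-level inferential statistics are out of scope; reports emit
per-participant metrics.

## Numerical choices and limitations

- Filtering renormalizes over the slice-retained states (remainder mass
  is dropped, not carried); a documented approximation.
- Zero-probability observations raise informative errors naming the
  trial; they cannot occur for models with strictly positive rows.
- Dirichlet proposals floor components at 1e-10 to avoid degenerate
  draws; simplex rows are validated to 1e-10 row-sum tolerance.
- The truncated-prior MH sampler does not prune redundant states at desk
  scale: occupied-state counts (reported by `diagnostics`) sit near 6
  for both 4-state and 8-state ground truths and should not be read as a
  model-complexity estimate from short chains. Free-structure CT chains
  can also settle in different modes at desk scale; `diagnostics` flags
  cross-chain spread, and prediction averages over chains.
- Held-out RT R² is bounded by the reciprocal-normal noise floor, which
  varies strongly between datasets (heavy right tail); subjective-
  probability recovery is the stable quantity (≥ 0.9 at desk scale for
  in-family ground truths, degrading gracefully at one training block).
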