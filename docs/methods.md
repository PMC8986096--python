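# Methods

## Task model

The simulator reproduces the generative structure of the odor-guided
two-well choice task. A session is four blocks: two delay blocks, then two
magnitude blocks. Within a block exactly one side holds the better outcome
(short delay, or big reward); the assignment of the first block is
randomized per session, every block switch reverses it, and the switch
from delay to magnitude context carries the contingency over — the well
that was "short" at the end of block 2 becomes "small" (now the worse
option) in block 3. Rewards are 1 or 2 drops; the delay is 0.5 s for
short/small/big outcomes and staircase-controlled within [1, 7] s for the
long outcome. Odor sequences are built per 20-trial window: 7 free-choice
trials and 13 forced trials split 7/6 between sides (the side with 7
alternating across windows), shuffled within the window by the seeded RNG.
This makes the free-choice fraction exactly 7/20 whenever the session
length is a multiple of 20.

Block lengths are drawn as round(Normal(mean, sd)) with defaults mean 70,
sd 14, rejected below a floor of 20 trials. The floor sits more than 3.5 SD
below the mean, so the sample moments are unaffected at Monte-Carlo
precision; the family itself (only the moments are specified externally)
is a design choice.

### Staircase

The published rule for titrating the long delay lives in the primary task
literature, so the simulator implements the simplest rule with the stated
behavior: a weighted up/down step on free-choice trials in delay blocks.
Choosing long raises the delay by `2·step·(1 − target)` and choosing short
lowers it by `2·step·target` (default step 0.5 s, target 0.5, i.e. the
symmetric ±0.5 s rule), always clamped to [1, 7] s. The equilibrium
long-choice fraction of this rule is `target`, which a closed-loop test
verifies against a delay-averse stochastic chooser. Both step and target
are configuration, not constants.

### What the generator does and does not emulate

It emulates block structure, odor statistics, reward contingencies,
reversals and the staircase — everything the choice models see. It does
not model odor-port timing, omitted or aborted trials (every trial yields
a choice), reaction times, or session-to-session drift in motivation.
Tests passing on this synthetic task therefore validate the *pipeline*
(simulation → likelihood → fitting → comparison), not claims about any
particular animal dataset.

## Learning and choice rules

All four models share delay-discounted Rescorla–Wagner learning,
`V ← V + η(γ^d r − V)`, a decision variable `DV(a) = V(s_a) + b·I[a=right]
+ p·I[a=prev]`, and a lapse-mixed softmax with inverse temperature β.
Parameter ranges: η, γ, λ ∈ [0, 1]; β ≥ 0 (fit within [0, 20]); b, p real
(fit within [−5, 5]); w₄ ∈ [0, 1]; η_g ∈ [0, η].

Design choices where the rules underdetermine an implementation:

* **Initial values** are 0 for all states at the start of every session,
  with no carry-over across sessions; this makes the first trial exactly
  indifferent (P(left) = 0.5 with b = p = 0) for all models.
* **Unrewarded outcomes**: with r = 0 the discount γ^d is irrelevant; the
  delay is ignored on those trials.
* **λ (lapse)** is a free parameter by default but can be frozen via the
  `fixed=` argument of the fitting functions, supporting both readings of
  which parameters are "free".
* **Hybrid-learning generalization** updates the paired same-side state
  (forced ↔ free) toward the same target γ^d r but relative to *its own*
  current value, and applies only on valid trials; invalid forced choices
  update only their own state with r = 0. Together with equal
  initialization this makes η_g = η collapse exactly onto the four-state
  model, and η_g = 0 onto the six-state model — both equalities are tested
  to 1e−12.
* **Hybrid-value** keeps both tables learning on every trial (the
  four-state NoRwd states update with r = 0 on invalid trials), and mixes
  values only at decision time with a single shared η and γ.
* **Perseveration** references the immediately preceding trial of the same
  session regardless of its trial type.

The likelihood inner loop is numba-compiled; the pure-Python
`trial_step` path is the readable reference implementation and the two are
pinned together by tests. A frozen five-trial hand-worked oracle checks
the arithmetic end to end at 1e−10.

## Fitting

**MLE** (`fit_mle`): bounded L-BFGS-B from random multistarts (default 10;
the large validation suites use 4–6) plus a midpoint start. The
hybrid-learning constraint η_g ≤ η is enforced by fitting ρ = η_g/η ∈
[0, 1]. Point fits report an AIC-style criterion −2ℓ + 2k, with the
penalty spread evenly over trials for paired comparisons; WAIC is
undefined for a single likelihood evaluation.

**Hierarchical Bayesian** (`fit_hierarchical`): each animal's parameters
are drawn from group Normal distributions on transformed scales — logit
for η, γ, λ, w₄ and ρ; log for β; identity for b and p — with Normal(0,
2.5) hyperpriors on group means and HalfNormal(1) on group SDs. Sampling
uses the affine-invariant ensemble sampler (emcee) with 2·dim + 2 walkers,
default 2000 steps with 1500 discarded as warm-up (reduced settings are
used in tests and experiments), initialized near quick per-animal MLEs.
WAIC is computed from a thinned posterior pointwise log-likelihood matrix;
the "group mean" reported on the constrained scale is the back-transformed
group-mean of the transformed parameter. Convergence diagnostics
(acceptance fraction, split-R̂ on the group means treating walkers as
chains — a conservative statistic for ensemble samplers) are attached to
the result and flag, never raise.

**WAIC**: waic = −2(lppd − p_waic) with lppd_i = log mean_s exp(ll_si) and
p_i the *unbiased* across-sample variance of ll_si; the standard error is
sd of per-trial contributions × √T, and ΔWAIC standard errors use the
paired per-trial differences. The decomposition identity and a closed-form
two-sample toy case are tested exactly; a cross-check against arviz agrees
after accounting for its population-variance convention.

## Behavioral analyses

**Generalization cases**: each incorrect free choice opens at most one
case, closed by the next free-choice trial; intervening *valid* forced
trials are counted. Cases are truncated at block switches by default
(the "better option" changes meaning there); `span_blocks=True` restores
unrestricted spanning. The hierarchical logistic regression of case
outcome on the count (raw scale; the optional within-block trial-index
covariate is divided by 10 only to keep the sampler well-scaled) uses the
same group-Normal/ensemble-sampler machinery; a fast per-animal logistic
fallback (`method="mle"`) exists for smoke tests.

**Learning curves**: accuracy (choosing the better option for the trial
type) at offsets −10..−1 and 1..10 around each block switch, averaged
within animal first, with s.e.m. across animals; empty offsets are NaN,
never zero.

## Experiments and problem sizes

The canned studies run at desk scale, chosen to finish in minutes on one
CPU while leaving the effects clearly resolvable: parameter recovery uses
20 agents × 20 sessions per model; identifiability 20 replicates × 30
sessions per generator; the reward-vs-w₄ curve 150–200 sessions per grid
point; the regression signature 8 agents × 12 sessions. The "average rat"
parameter set used by forward simulations (η = 0.25, γ = 0.8, β = 3,
b = 0, p = 0.2, λ = 0.02) is a documented plausible regime, *not* a fitted
estimate — the original cohort's data and posteriors are not public, which
is also why recovery and identifiability studies stand in for re-fitting
real data. Agent populations for recovery draw η ~ U(0.1, 0.5), γ ~
U(0.5, 0.95), β ~ logU(1.5, 6), b, p ~ N(0, 0.3), λ ~ U(0, 0.1), and
w₄, ρ ~ U(0.05, 0.95). Every experiment derives all child seeds from one
integer via `SeedSequence` and records them in its manifest; re-running
with the manifest seeds reproduces the tables exactly.

## Known limitations

* The ensemble sampler mixes slowly in high-dimensional hierarchical
  posteriors; at the reduced settings used in tests the group-level R̂ can
  exceed textbook thresholds even when posterior means are accurate. For
  publication-grade posteriors increase steps/walkers or swap in an HMC
  backend behind the same interface.
* MLE point fits of weakly identified parameters (γ at short delays, λ)
  inherit the usual boundary issues; the recovery study quantifies this.
* The split-half analysis splits sessions chronologically in half per
  animal and assumes stationarity within halves.
* Simulated cohorts are balanced by default; real cohorts rarely are. An
  unbalanced design can be built by calling the simulator per animal.
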