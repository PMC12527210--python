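# Methods

## Task model

Time is discretised into 1-second bins.  A block is `duration_bins` (default
120) bins of free responding under a fixed contingency (P1 = P(O|A),
P2 = P(O|~A)).  Within a bin at most one response is possible (the lockout
holds by construction: a bin's `responded` flag is Boolean).  The outcome
for a bin is evaluated once, at bin end: Bernoulli(P1) if the bin contained
a response, Bernoulli(P2) otherwise, and delivery occurs within the same
bin.  Nothing below 1-s resolution is modelled — no reaction times, no
within-bin event ordering, no stimulus rendering.

Two contingencies are used: training ΔP = +0.6 (P1 = 0.6, P2 = 0) and
habit-test ΔP = −0.3 (P1 = 0.6, P2 = 0.9).  Type invariants enforce that
training blocks have ΔP > 0 and habit-test blocks ΔP < 0.

## Schedules

Per-participant schedules follow the three variants' block economies
exactly (24 overtrained / 6 standard positive blocks; 2 + 2 filler blocks
in the variants that include a filler; 22 positive blocks in session 2).
Training order within a session is pseudorandomized: half of each cue's
blocks in uniform random order, then the second half in a fresh random
order (`pseudorandomize_order`; precondition: even per-cue counts).
Session 3 alternates two training blocks (one per tested cue) with two
habit-test blocks, twice.  The O/S order within session-3 pairs is the
participant's test order: an unconstrained fair coin per participant in
variant 1 (which therefore produces unequal between-subject group sizes,
as intended), and the counterbalance group (A = overtrained first,
B = standard first) in variants 2–3, alternated by participant index in
simulated cohorts.  Since the coin is drawn after the session-1/2 orders,
groups A and B of the same seed differ only in session-3 order.

Schedules are byte-reproducible from `(variant, participant_id, seed,
group)` via `numpy`'s PCG64 seeded with `[seed, participant_id]`.

## Agent model (synthetic; no fit to human data)

The generator exists to produce cohorts with the statistical structure the
analysis assumes, not to model human learning.  Per cue, an agent carries
beliefs `p1_belief`, `p2_belief` and a habit strength H.  Each bin:

1. respond with probability `logistic(b + β·(p1_belief − p2_belief) + w·H)`
   (`b` = baseline_logit, `β` = inverse_temperature, `w` = habit_weight);
2. sample the outcome from the environment (above);
3. update the belief of the experienced branch by the delta rule with step
   `learning_rate`; if the bin was a reinforced response, `H += habit_gain`.

H is cue-specific, never transfers, and is nondecreasing during training;
beliefs persist across blocks and sessions of a cue (no reset), beliefs
start at (0.5, 0.5).  At block end the causality rating is
`round(clip(100·(p1_belief − p2_belief) + ε, −100, 100))` with
ε ~ N(0, rating_noise_sd²), and the memory test succeeds with probability
`1 − memory_error_rate`.

Presets (defaults chosen once, as the study conditions):

* **goal_directed** — α = 0.12, β = 5, no habit terms, b = −0.8,
  rating noise SD 15, memory error 0.01.  Converged training responding is
  `logistic(−0.8 + 5·0.6) ≈ 0.90` per bin, inside the 0.83–0.92 band human
  cohorts show on this task; at test the believed ΔP goes negative and
  responding collapses.
* **habitual** — α = 0 (contingency-blind), β = 0, habit_gain = 1,
  habit_weight = 0.0015, b = 0.5.  Responding is driven by accrued habit;
  since the policy ignores the contingency, test responding matches
  training responding and ratios sit at ≈0.5.  Ratings hover around 0
  (frozen beliefs), which is deliberate: this phenotype never detects the
  degradation.
* **mixed** — per-participant α ~ U(0.005, 0.25), β ~ U(1.5, 7),
  habit_weight ~ U(0, 0.001).  Heterogeneous contingency detection
  produces the negative correlation between test-block ratios and
  causality ratings that individual-difference analyses target:
  participants who still believe the response causes the outcome keep
  responding.

What the generator does **not** emulate: within-session fatigue or drift,
reaction times, attention lapses correlated across blocks, rating biases
(anchoring, scale avoidance), or any strategic/explicit reasoning.  Tests
passing on these cohorts therefore validate the *pipeline* (environment
fidelity, estimator correctness, calibration of the statistics), not any
claim about human behaviour.

## Measures

* Experienced contingency per block: conditional outcome proportions;
  a conditional with an empty denominator is NaN, and NaN propagates to
  ΔP̂.  Undefined values are excluded listwise from analyses and their
  counts reported in the `missing` section of the report — the paradigm's
  summaries are silent on this, and visible missingness beats imputation.
* "Last two training blocks" (within-subject baseline) means: the last two
  same-cue positive blocks preceding the cue's *first* habit-test block.
  For session-3 cues only one session-3 training block precedes the first
  test, so the rule reaches back to the cue's latest session-2 block; for
  the filler cue it selects its two session-1 blocks.  The between-subject
  variant uses one baseline block and the first test block only.
* Inclusion: memory accuracy across all blocks ≥ 0.9, endpoint included.

## Statistics

* t-tests report one-tailed p in the stated direction.  Directional
  conventions: sensitivity tests are `ratio > 0.5`; overtraining contrasts
  are tested on (standard − overtrained) and (filler − overtrained)
  differences with alternative "greater", so habit-consistent data give
  t > 0 and null/opposite data give p near .5–1 in the conventional sign
  pattern.  The exact published form of the sensitivity test is ambiguous
  between this one-sample form and a paired train-vs-test-rate form; the
  pipeline uses the one-sample ratio form and labels it as such, and
  `paired_t` is available for the other.
* The between-subject comparison uses the pooled-variance form unless a
  two-sided F pre-check rejects variance equality at α = .05, in which
  case the Welch form is applied and flagged in the report
  ("when necessary" made explicit).
* Zero-variance samples return an error-flagged result rather than raising,
  with one convention: a sample constant at the null value is t = 0,
  p = 0.5.  Constancy is judged at a scale-relative tolerance (1e−12)
  because float accumulation makes `std([0.7]*3)` nonzero.
* Bayes factors are two-sided default JZS factors: Cauchy(0, 0.707) prior
  on the standardized effect, marginal likelihood computed by adaptive
  quadrature of the noncentral-t density over the prior after the
  substitution δ = r·tan(θ) (absolute tolerance 1e−10; the ML-effect
  location is passed as a breakpoint because the integrand is a narrow
  spike for large |t|).  One-sided BFs are not used.  For Welch tests the
  BF uses the standard two-sample JZS form (integer df), matching common
  software defaults.  No multiple-testing correction is applied anywhere,
  matching the pre-registered analysis style this reproduces.
* The sample-size solver inverts the exact noncentral-t power function by
  doubling + bisection; d_z = 0.4, 80% power, two-tailed α = .05 gives
  n = 52 (> 50, the planning benchmark for within-participant designs).
* Correlations involving programmed vs experienced ΔP are emitted in two
  aggregations (block-pooled and participant-cue-phase means), since
  published single-r summaries are ambiguous between them; neither is
  privileged.

## Determinism and numerics

All randomness flows through `numpy.random.Generator` (PCG64).  Cohort
seeds spawn per-participant `SeedSequence` children; design randomness uses
`[seed, participant_id]`.  The block simulator pre-draws a `(bins, 2)`
uniform array (response, outcome per bin) and a unit test asserts the fast
path is bit-identical to scalar `step_bin` stepping.  Report JSON is
serialized with sorted keys and floats rounded to 4 decimals, so identical
config + seed ⇒ byte-identical reports; the numpy version and RNG algorithm
are recorded in the report header.

## Problem sizes

Default problem sizes keep everything desk-scale: simulated cohorts of
50 participants (38 blocks × 120 bins each, ≈0.3 s per cohort), 2,000
blocks for the environment-fidelity estimate, 100 replicate cohorts for
phenotype recovery, and 10,000 null datasets for p-calibration.  These were
chosen as the sizes at which the binomial/KS tolerances used in the test
suite are meaningful.

## Known limitations

* The agent model is a three-parameter caricature; it cannot produce
  dissociations between stated beliefs and behaviour beyond what rating
  noise induces.
* Habit strength is unbounded; the habitual preset relies on logistic
  saturation rather than an asymptote.  Ratios stay at ≈0.5 because the
  policy is contingency-blind, not because habit growth stops at test.
* The event-log CSV contract is the only ingestion path for real data;
  no converters from native repository formats are included.
* Outcomes are delivered in the same bin as the triggering response; a
  next-bin delivery convention would shift experienced-ΔP estimates only
  at block edges but is not implemented.
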