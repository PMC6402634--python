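# Methods

This note documents the models behind `gonogo`: what is simulated, which
parameters matter, what the synthetic cohort does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Schedule generation

Valence sequences satisfy two constraints jointly: a maximum run of
`max_run` (default 3) identical valences, enforced globally (a run may not
straddle a block boundary to exceed the limit), and an exact 1:1 S+:S-
ratio in every complete block of `block_size` (default 100) trials.

The sampler is constructive, not rejection-based: trials are drawn one at a
time, and a candidate valence is admitted only if the remaining block
budget can still be arranged without violating the run constraint. The
feasibility test is the standard gap-capacity argument: with `p` trials of
the running valence and `q` of the other left in the block, and a trailing
run of length `ℓ`, an arrangement exists iff `p ≤ (max_run − ℓ) + max_run·q`
and `q ≤ max_run·(p + 1)`. A block ending in any legal run can always be
continued into the next (balanced) block, so within-block lookahead
suffices. Both feasible valences are equally likely at each step; this does
not weight sequences exactly uniformly, but gives every valid sequence
nonzero probability and is verified against exhaustive enumeration at small
n. Termination is guaranteed — an infeasible parameter combination raises
immediately rather than hanging.

Partial final blocks (n not a multiple of 100) are balanced to within one
trial, with the odd trial's valence chosen at random. A cohort's reward
mapping splits the animal list into ceil/floor halves after a seeded
shuffle; all animals share one valence sequence while the two halves
receive opposite physical odours on S+ trials.

Pre-training is three stages (10 / 50 / 100 trials): free water on port
entry, at least one lick anywhere in the window, then a required licking
fraction ramping linearly from 1% up to 10% of the 2 s trial length. The
ramp shape is a design choice; only the endpoint (10%) is given by the
protocol it models.

## Olfactometer model

Delivered concentration is linear in the commanded mass-flow-controller
fraction, normalised so full flow gives a plateau of 1; absolute vapour
concentrations are intentionally out of scope and all traces are in
relative units. Pulse kinetics are single-exponential with
`τ = rise_time_90 / ln 10`, so the noiseless trace crosses 90% of plateau
exactly 20 ms (default) after onset — the kinetic form is the simplest one
consistent with the single calibration point available. The sampling grid
is 1 kHz by default, ample for a 20 ms rise.

In divert mode the final valve sends the odour stream to exhaust: the mean
trace is identically zero whatever stimulus is configured, which is the
property that makes final-valve diversion a chance-performance control.
Measurement noise is additive Gaussian, symmetric about the signal; only
the upper physical bound (1.05) is clipped so that a zero signal keeps zero
mean. Residual final-valve contamination is deliberately *not* modelled as
an informative signal — it is common to all stimuli — and is omitted by
default.

Two control manipulations operate on configs and plans: valve introduction
re-draws combinations from the enlarged set only from the switch trial on,
leaving everything else untouched; a full bottle switch permutes physical
bottle positions while the software remap keeps every valve's logical
odour, so enumerated combination sets are stimulus-equivalent before and
after.

## Trial controller

Door logic is a pure disjunction: any blocked beam closes the door, all
clear springs it open, guaranteeing single occupancy. Quarter boundaries
are half-open `[start, end)` against *absolute* interval edges (a lick on
an internal boundary belongs to the later quarter; this also avoids float
drift between relative and absolute time). Lick contacts closer than 20 ms
merge (lickometer debounce). The RFID identity is latched at trial
initiation; a read failure aborts the visit with a warning and no record.
Timeout ITIs are uniform on [8, 12] s. Timestamps are float seconds since
the experiment epoch. An imposed ITI is honoured across visits: a returning
animal cannot start a trial before the previous trial's ITI has elapsed.

## Cohort simulator

The simulator's purpose is statistical: it reproduces the *structure* the
analyses assume, not mouse biology.

**Circadian activity.** Trial initiations follow an inhomogeneous Poisson
process with hourly rates from a two-term cosine density fitted (once, at
first use) to three constraints: a stationary trough in the 7th light-phase
hour (15:00–16:00), a stationary peak 15 h later (06:00–07:00), and a
dark-phase (21:00–09:00) mass of 0.61. The 0.61 night fraction in simulated
data is therefore a *calibration*, not a discovery, and tests assert it as
such. Session structure is a burst process: session start times follow the
circadian density, lengths are geometric with mean 38 trials.

**Water budget.** Daily water target is affine in weight,
`target = 300 + 70·weight_g` µl (a 25 g mouse targets ≈ 2 ml/day), chosen
so that a 12 µl reward yields ≈ 340 trials/day and the 10–30 µl reward
range spans roughly 150–560 trials/day. Expected daily trials are
`target / (reward × hit fraction)` — trials × reward ≈ constant — with a
compensation ceiling of 1.5× the 12 µl baseline for smaller rewards:
animals do not fully make up very small rewards with extra activity. The
ceiling value is a modelling choice pinned only by the qualitative
under-compensation it must produce.

**Learning.** One scalar association `a ∈ [0, 1]` per odour pair (mixture
versions of a pair, and auditory pairs, are separate keys), updated by a
delta rule `a ← a + λ(1 − a)` on every completed trial. Response
probability is `P(pos|S+) = b + (1−b)·d` and `P(pos|S−) = b·(1−d)` with
discriminability `d = 2a(asymptote − 0.5)`, base lick rate `b = 0.5`, and a
lapse fraction responding at random — so a naive agent is valence-blind and
expected performance is `0.5 + a(asymptote − 0.5)(1 − lapse)`. Defaults
λ = 0.01, asymptote = 0.95, lapse = 0.02 put initial-pair acquisition in
the observed 54–398-trial range and familiar-pair recognition in the
20–46-trial range. Mixture associations learn at half the base rate, which
yields the observed task-difficulty ordering (familiar > novel/NTS >
mixture/NTM) in pooled first-100-trial performance. The learning rule is
this package's central modelling invention; the experiments it emulates
report learning curves but prescribe no model.

**Lesions.** Presets keyed by injected NMDA amount (sham, S 303.6, M 607.2,
L 1214, XL 1669.8, XXL 2125 ng) map to phenotype parameters rather than a
continuous dose-response curve: recognition loss (stored odour associations
reset at lesion time, auditory spared) from the smallest lesions up;
reduced olfactory learning rate and an asymptote penalty on non-trigeminal
tasks for large lesions, with a trigeminal-bypass floor on trigeminally
active odour pairs; complete anosmia (odour-task association pinned at 0,
auditory learning fully intact) at the largest amount. Preset magnitudes
are calibrated only to reproduce the qualitative group orderings.

**What the simulator does not emulate.** Single-port competition between
animals (per-animal visit streams are merged, collisions ignored),
motivational drift, satiety within a session, odour-similarity structure
(all discriminations of a class are equally hard), and any biophysics of
the olfactory bulb. A green simulation-based test therefore establishes
that the *pipeline* behaves correctly on data with the assumed statistical
structure — not that real mice behave this way.

**Randomness.** All stochastic draws flow from one seed through
`numpy.random.SeedSequence` spawning: one stream per agent plus separate
streams for schedule building, visit generation and ITI draws. Identical
seeds give byte-identical schedules, event logs and analysis tables.

## Analysis

Windows lacking a valence class yield an explicit undefined marker (NaN),
excluded from aggregates — with max-run 3 and windows ≥ 10 this is rare,
and imputation would bias early-trial estimates. TTC when the criterion is
never reached is an explicit not-reached marker (None), excluded from TTC
means with reported n. The night/day boundary is inclusive at 21:00.
Sessions shorter than a scoring window (or containing one valence class
only) are excluded from the session-length/performance correlation, with
the count available. t-tests are two-tailed, correlations Pearson, and the
task-context omnibus is a one-way ANOVA with Tukey-Kramer-corrected
pairwise comparisons (via statsmodels). Group curves are mean ± sem.

One property worth noting: "prepending correct trials cannot delay the
criterion" holds only in shift-adjusted form. Window realignment can move
the first crossing later by up to the number of prepended trials (never
more); a full prepended window of correct trials reaches criterion
immediately. The property test asserts exactly this.

## Known limitations

- The valence sampler's per-step coin flip is not an exactly uniform
  sampler over the constrained sequence set (it is verified to cover the
  set with nonzero probability everywhere).
- Water accounting is exact in expectation but overdispersed day to day
  because session lengths are geometric; conservation tests pool days.
- Detection tasks model clean air as a blank source; reward reversal is
  not applied to detection tasks.
- The event-log format fixes four response quarters per trial.
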