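# Methods

This note documents the generative model, the processing rules, the
statistical machinery, and the design choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model

A session consists of a go-only block (30 trials), a reactive practice block
(30), five reactive main blocks of 60 trials (40 go / 10 left-stop /
10 right-stop each), a proactive practice block (30), and ten proactive main
blocks of 54 trials (per cue: 18 go / 9 stop each).  Go trials require a
synchronous bimanual press (synchrony: the two presses within 50 ms); on stop
trials one arrow turns red after the stop-signal delay (SSD) and only that
hand must be cancelled.  The reactive/proactive order is a config flag
(default reactive first); counterbalancing across a cohort is the caller's
responsibility.

TMS is allocated to main-block trials from a config-driven table.  The
default table treats the dual-coil CSE measurement as a single trial type
that yields MEP records in both hands; with the four conditioned pathway
types (SIHI_LR, LIHI_LR, SIHI_RL, LIHI_RL) this gives five trial-level TMS
types, and the allocation

- reactive: 10 per type at each of WS/IS/IS150 on go trials + 20 per type at
  SS150 on stop trials (half left, half right) = **250**,
- proactive, per cue: 10 per type at WS/IS/IS150 (go) and SS150 (stop) + 20
  CSE at IS and 20 CSE at IS150 on stop trials = 240, both cues = **480**,

sums exactly to the published totals with no remainder.  Cells are stratified
across blocks (equal share ±1 per block, remainder placed by seeded draw).
At the default block counts every cell divides evenly.  Reduced designs keep
the same per-block stimulation rates.  The 50 pre-session calibration TMS
trials are generated as a separate practice-phase sequence
(`build_calibration_block`) and excluded from main-block counts.

## Generative model (synthetic_data)

**Go process.**  Both hands share one finishing time
`T = shift + exp(N(mu, sigma))` (shift 150 ms; `mu`, `sigma` solved in closed
form from the configured mean/SD, default 430/89 ms) plus independent
per-hand synchronisation jitter (SD 19 ms, chosen so that ~7% of go trials
are asynchronous at threshold 50 ms).  Proactive cueing adds a constant go
slowing (default 17 ms).  Each hand independently omits its press with
probability `p_omission` (default 0.003), producing Incomplete/Missed
outcomes.  Responses slower than the go-only-block mean + 250 ms receive the
"Respond quicker" flag; they are valid synchronous responses and are treated
as correct throughout (the flag is motivational feedback, not an error).

**Stop process.**  The stop latency is deterministic per subject and
condition (default 268 ms reactive, 278 ms proactive), which makes the
integration-method recovery well-posed.  On a stop trial the cued hand is
cancelled iff its finishing time exceeds `SSD + SSRT` (independent race).
SSDs staircase 1-up/1-down in 50 ms steps from 200 ms with a 50 ms floor,
independently per hand x condition (reactive) and per hand x cue (proactive);
with a continuous go distribution this targets a 50% response rate on stop
trials.  Responses before the stop-signal (both finishing times < SSD) are
premature responses; they count as responses for the staircase, as do
wrong-hand stops (flag-configurable).  Missed stop trials (no press at all)
leave the staircase unchanged — neither success nor failure is evidenced.

**Stopping interference.**  On successful stops the continuing hand's press
is *re-programmed*: its recorded RT is an independent redraw of the go
finishing time multiplied by a condition-specific interference factor
(defaults 1.22 reactive / 1.16 proactive).  A re-draw rather than a scaling
of the trial's own finishing time is used deliberately: conditioning on the
stop side winning the race selects slow shared finishing times, which would
add a large selection artefact (~+15% at default parameters) on top of the
planted multiplier and make the planted elongation unidentifiable.  The
re-programming account also matches the empirical signature that the
continuing response is time-locked to the stop-signal rather than the
imperative signal.  Under it, the expected stop-vs-go elongation equals the
planted multiplier exactly, and mean signal-respond RT < mean go RT (failed
stops select fast trials) still holds.

**MEPs.**  Amplitudes are Gamma(shape 2.5) with mean
`gain_subject x scale[hand_status] x (ratio[pathway, hand_status] if
conditioned)`.  The default status means (mV) and LIHI/SIHI ratios are set to
the observed posterior medians of the corresponding real-data quantities so
that synthetic cohorts live on a realistic scale; between-subject gain is
lognormal (SD 0.25 on the log scale).  Pre-pulse RMS EMG exceeds the 0.025 mV
exclusion threshold with probability 0.022.  Conditioned trials yield one
record in the pathway's test hand (LR pathways → left hand, RL → right); CSE
trials yield two records sharing the trial id.

## Behavioural processing

Correct-RT filtering keeps correct go trials and successful stops with the
relevant RT > 200 ms (fast-guess exclusion); stop RTs are reported both
relative to the imperative signal and relative to the stop-signal
(RT − SSD).  The go RT of a trial is the mean of the two press times; the
hand-specific go pools used for SSRT take that hand's press time (the race is
hand-specific).  p(respond | stop signal) counts failed stops, premature
responses and wrong-hand stops as responses; missed stop trials stay in the
denominator (flag-configurable).

**SSRT (integration method).**  Go omissions are replaced with the maximum
observed go RT; go RTs are sorted ascending; the index is `ceil(p x N)`
clamped to [1, N] (the common integration-method convention; interpolation
variants exist and would differ by < 1 RT quantile step); SSRT is that go RT
minus the subject's mean SSD for the cell.  A cell is invalid (no estimate,
with a reason) when p < 0.25 or p > 0.75, or when mean signal-respond RT
exceeds mean go RT (race-model violation).  Every subject x condition x hand
cell yields exactly one estimate record.

## Bayesian models and posterior indices

Four families: shifted-lognormal (trial-level RTs; fitted on
`log(rt − shift)`, shift a config constant, default 0 so that multiplicative
effects on the whole RT are exactly identified), Gaussian (averaged SSRTs),
Gamma with log link (MEP amplitudes), Bernoulli with logit link (stopping
success).  Fixed effects use cell-means coding — one coefficient per
factor-level combination — so contrasts are transparent linear combinations
of named cells; marginal-mean contrasts average cells, interaction
(ratio-of-ratios) contrasts use explicit ±1 weights.

Random structure: by-participant intercepts plus by-participant cell
deviations with a shared SD (no correlations).  This is the first rung of
the usual simplification ladder from the maximal structure, applied up front:
with small simulated cohorts the maximal covariance is not identified, and
the shared-SD structure is what the data can support.  For the Gaussian-core
families the random effects are integrated out analytically (Woodbury
identity on per-subject sufficient statistics), leaving a handful of
population parameters to sample; the Gamma and Bernoulli families sample
subject intercepts explicitly.

Priors are flat (improper) on all population-level coefficients.  Variance
components get weakly-informative priors — Half-Normal on random-effect SDs
(scaled to the response's dispersion), flat-on-scale for the residual SD,
flat-in-log for the Gamma shape — because fully improper priors on variance
components lead to improper or boundary-degenerate posteriors with few
subjects.  Scale parameters are sampled directly on the positive scale.

**Sampling.**  Posteriors are sampled with affine-invariant ensemble MCMC
(emcee; 80% differential-evolution moves, 20% snooker moves), initialised in
a small ball around a numerically located posterior mode.  The nominal
draws-per-chain interface (default 8 chains x 1,500 post-warmup draws =
12,000) is mapped onto walkers x steps with floors of 1,200 warmup and 800
retained steps; walkers are treated as chains for the split-Rhat diagnostic,
flagged at Rhat ≥ 1.1 as a structured warning (never silently ignored).
Draws are bit-reproducible for a fixed seed and backend version.  A known
artefact: when the true random-effect SD is ~0, its posterior piles at the
boundary and its Rhat can flag spuriously; contrast coefficients are
unaffected.

**Indices.**  All computed from raw draws, no distributional assumptions:
pd = share of draws on the median's side of the null point (null 0, or 1 on
the ratio scale); 89% HDI = the shortest window of ceil(0.89 n) sorted draws
(ties → lowest window; n < 100 is refused as unstable); % of HDI in ROPE =
share of HDI-member draws inside the ROPE (draw-counting, not
interval-length overlap — the two differ for skewed posteriors); decision =
accept (HDI ⊆ ROPE), reject (HDI ∩ ROPE = ∅), else no decision.  ROPE
defaults: ±5 percentage points on the percent-change scale (ratio
[0.95, 1.05]); ±0.05 log-odds for the logistic model; ±5% of a stated
reference response for identity-link contrasts.  HDIs are computed on the
reporting scale (ratio/percent for log links), since HDIs are not invariant
under nonlinear transforms; the scale tag is stored with the draws.  The HDI
window convention (ceil(p·n) draws, exactly p mass) differs from
arviz/bayestestR (floor(p·n)+1 draws) by one order statistic.

**Model-entry rules.**  The Gamma MEP models use retained (EMG-clean),
correct-response observations; the CSE trials delivered at IS/IS150 on
proactive stop trials feed only the stopping-success logistic model, not the
Gamma models.  For execution/cancellation contrasts the three IS statuses
are collapsed to a single IS level; the conditioned and unconditioned groups
have identical status composition there, so the pooled conditioning ratio is
composition-unbiased.

## Problem sizes and what recovery shows

The test suite and acceptance script use: full 27-subject cohorts for design
counts, staircase calibration and SSRT recovery (~25k trials per cohort,
seconds to simulate); reduced 8-subject cohorts (2 reactive + 4 proactive
main blocks) with a 2-chain x 500-draw sampler profile for the
planted-effect recoveries.  At the reduced scale a single LIHI
ratio-of-ratios posterior is wide (the SS150-continuing cells hold only
~5–10 retained conditioned records per subject), so recovered values are
reported as means of contrast medians over repeated independent recovery
runs; coverage checks (89% HDI containing the planted value in ≥ 80% of
runs) are run over 5 seeded repeats.

Passing these tests shows that the processing rules implement their stated
definitions exactly and that the estimation chain is calibrated *under the
generator's assumptions*.  Real recordings differ in ways the generator does
not emulate: RT autocorrelation, fatigue and strategy drift, trigger
failures, SSRT variability, EMG artefact structure, and MEP dependence on
behaviour.  Recovery here is therefore a necessary, not sufficient,
validation for real-data use.

## Known limitations

- No parametric (e.g. ex-Gaussian/Bayesian) SSRT estimation and no
  trigger-failure-aware race models.
- The ensemble sampler is a gradient-free stand-in for NUTS-style samplers;
  it is well-suited to the marginalised models' low dimension but would not
  scale to maximal random-effect structures on large cohorts.
- Random-effect correlations are not modelled.
- Raw EMG traces are optional and synthetic traces are not physiologically
  detailed; `extract_mep` is exact for any supplied trace.
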